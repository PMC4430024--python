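"""Materialize a self-contained synthetic demo dataset.

Writes per-species promoter FASTAs for a small set of genes (orthologous
families with conserved blocks and planted binding sites), a 3'UTR FASTA,
narrowPeak files for two mock cell lines, JSON truth files and a ready
pipeline YAML config. Everything is reproducible from the seed.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from . import motif, seqio, synthetic_data

DEMO_SPECIES = {"human": 0.0, "chimpanzee": 0.1, "mouse": 0.4, "cattle": 0.3}
DEMO_GENES = ("IRF1", "NFKB1", "RELA")


def make_demo_dataset(outdir: Path, seed: int = 0) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pfms = {p.tf_name: p for p in motif.bundled_pfms()}
    per_species: dict[str, list[seqio.SequenceRecord]] = {
        sp: [] for sp in DEMO_SPECIES
    }
    truth_all = synthetic_data.SyntheticTruth()
    seq_lengths: dict[str, int] = {}
    for k, gene in enumerate(DEMO_GENES):
        plants = [
            (pfms["IRF1"], 120),
            (pfms["RELA"], 160),
            (pfms["SP1"], 620),
        ]
        records, alignment, truth = synthetic_data.generate_ortholog_family(
            length=1000,
            species_divergences=DEMO_SPECIES,
            conserved_blocks=[(100, 250), (600, 750)],
            pfm_plants=plants,
            seed=seed * 101 + k,
            gene=gene,
        )
        for sp, rec in records.items():
            rec = seqio.SequenceRecord(
                id=gene, seq=rec.seq, species=sp, role="promoter"
            )
            per_species[sp].append(rec)
            seq_lengths[gene] = len(rec.seq)
        for site in truth.planted_sites:
            # demo records are named by gene (one variant per species)
            sid = site.seq_id.split("_")[0]
            if site.seq_id.endswith("human"):
                truth_all.planted_sites.append(
                    synthetic_data.PlantedSite(
                        seq_id=sid,
                        interval=seqio.GenomicInterval(
                            sid, site.interval.start, site.interval.end,
                            site.strand,
                        ),
                        strand=site.strand,
                        tf_name=site.tf_name,
                        sampled_sequence=site.sampled_sequence,
                    )
                )
        truth_all.conserved_blocks.extend(truth.conserved_blocks)

    paths: dict[str, Path] = {}
    for sp, recs in per_species.items():
        p = outdir / f"promoters_{sp}.fa"
        seqio.write_fasta(recs, p)
        paths[f"promoters_{sp}"] = p

    utr_specs = {"IRF1": (4, 1, 8, 0.5, 2100), "IRF3": (0, 0, 0, 0.425, 89)}
    utrs = []
    for j, (gene, (n1, n2, n3, at, length)) in enumerate(utr_specs.items()):
        rec, utr_truth = synthetic_data.generate_synthetic_utr(
            n1, n2, n3, at_target=at, length=length,
            seed=seed * 307 + j, utr_id=f"{gene}_3UTR",
        )
        utrs.append(rec)
        truth_all.are_sites.extend(utr_truth.are_sites)
    paths["utr3"] = outdir / "utr3.fa"
    seqio.write_fasta(utrs, paths["utr3"])

    for i, cell_line in enumerate(("cellA", "cellB")):
        peaks = synthetic_data.generate_peak_file(
            truth_all, coverage_fraction=0.8, seq_lengths=seq_lengths,
            jitter_bp=20, n_decoys=2, seed=seed * 509 + i, cell_line=cell_line,
        )
        p = outdir / f"peaks_{cell_line}.narrowPeak"
        synthetic_data.write_narrowpeak(peaks, p)
        paths[f"peaks_{cell_line}"] = p

    paths["truth"] = outdir / "truth.json"
    truth_all.to_json(paths["truth"])

    config = {
        "promoters": {sp: str(paths[f"promoters_{sp}"]) for sp in DEMO_SPECIES},
        "reference_species": "human",
        "utr3": str(paths["utr3"]),
        "peaks": {
            "cellA": str(paths["peaks_cellA"]),
            "cellB": str(paths["peaks_cellB"]),
        },
        "background_n": 25,
        "background_seed": seed,
    }
    paths["config"] = outdir / "config.yaml"
    paths["config"].write_text(yaml.safe_dump(config))
    return paths
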