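"""Config-driven orchestration of the full promoter analysis.

``run_pipeline`` wires the stages together: motif scanning of every
promoter in every species, pairwise cross-species conservation filtering
against a reference species, per-promoter count tables, promoter
GC-composition with cofactor (AP-1/SP1) counts, 3'UTR ARE classification,
random-background specificity, and ChIP-seq peak support. The output
bundle is a directory of TSV/BED/JSON files plus a run log recording every
parameter and seed, and is a pure function of (config, input files, seeds).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import are_utr, background, chipseq_xref, conservation, motif, seqio, summarize

DEFAULT_MEMBERS_OF_INTEREST = ("IRF3", "REL")


class PipelineError(RuntimeError):
    """A stage failure; the message names the stage and the offending input."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """All paths and parameters of a run. Every analysis parameter the
    underlying method leaves open has an explicit default here, so the open
    choices are visible in one place."""

    promoters: dict[str, str] = field(default_factory=dict)  # species -> FASTA
    reference_species: str = "human"
    utr3: Optional[str] = None
    pfm_file: Optional[str] = None  # None -> bundled synthetic matrices
    peaks: dict[str, str] = field(default_factory=dict)  # cell line -> peak file
    alignment_dir: Optional[str] = None  # per-gene CLUSTAL files (optional)

    rel_threshold: float = motif.DEFAULT_REL_THRESHOLD
    pseudocount: float = motif.DEFAULT_PSEUDOCOUNT
    members_of_interest: tuple[str, ...] = DEFAULT_MEMBERS_OF_INTEREST

    cons_window: int = conservation.DEFAULT_WINDOW
    cons_min_identity: float = conservation.DEFAULT_MIN_IDENTITY
    cons_min_len: int = conservation.DEFAULT_MIN_LEN
    cons_min_col_overlap: float = conservation.DEFAULT_MIN_COL_OVERLAP

    are_params: are_utr.AREParams = field(default_factory=are_utr.AREParams)

    background_n: int = 100
    background_length: int = 1000
    background_seed: int = 0
    background_composition: tuple[float, float, float, float] = background.UNIFORM
    background_tfs: tuple[str, ...] = ("JUN", "SP1")

    align_match: float = 1.0
    align_mismatch: float = -1.0
    align_gap: float = -2.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        try:
            raw = yaml.safe_load(Path(path).read_text()) or {}
        except (OSError, yaml.YAMLError) as exc:
            raise ConfigError(f"cannot read config {path}: {exc}") from exc
        are_raw = raw.pop("are_params", None)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if are_raw:
            cfg.are_params = are_utr.AREParams(**are_raw)
        for k in ("members_of_interest", "background_tfs", "background_composition"):
            setattr(cfg, k, tuple(getattr(cfg, k)))
        return cfg


def _gene_variant(record_id: str) -> tuple[str, str]:
    """Record ids follow ``GENE`` or ``GENE.variant``."""
    gene, _, variant = record_id.partition(".")
    return gene, variant or "1"


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run every configured stage; write the report bundle under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: list[str] = []

    def note(msg: str) -> None:
        log.append(msg)

    note("crossreg pipeline run")
    note(f"parameters: {json.dumps(_config_dict(config), sort_keys=True)}")

    # --- stage: load motifs -------------------------------------------------
    try:
        if config.pfm_file:
            pfms = motif.load_pfm_file(config.pfm_file)
        else:
            pfms = motif.bundled_pfms()
        pwms = [motif.pfm_to_pwm(p, pseudocount=config.pseudocount) for p in pfms]
        family_map = {p.tf_name: p.family for p in pfms}
    except Exception as exc:
        raise PipelineError("motifs", str(exc)) from exc
    note(f"loaded {len(pwms)} matrices: {', '.join(p.tf_name for p in pwms)}")

    # --- stage: scan promoters ---------------------------------------------
    promoters: dict[str, list[seqio.SequenceRecord]] = {}
    hits_by_record: dict[tuple[str, str], list[motif.MotifHit]] = {}
    all_hits: list[motif.MotifHit] = []
    try:
        for species, path in config.promoters.items():
            promoters[species] = seqio.read_fasta(path, species=species, role="promoter")
            for rec in promoters[species]:
                rec_hits: list[motif.MotifHit] = []
                for pwm in pwms:
                    rec_hits.extend(
                        motif.scan(pwm, rec, rel_threshold=config.rel_threshold)
                    )
                hits_by_record[(species, rec.id)] = rec_hits
                all_hits.extend(rec_hits)
    except Exception as exc:
        raise PipelineError("scan", str(exc)) from exc
    outputs: dict = {}
    if promoters:
        motif.write_hits_tsv(all_hits, outdir / "hits.tsv")
        motif.write_hits_bed(all_hits, outdir / "hits.bed")
        outputs["hits"] = outdir / "hits.tsv"
        note(f"scanned {sum(len(v) for v in promoters.values())} promoters, "
             f"{len(all_hits)} hits at rel_threshold={config.rel_threshold}")

    # --- stage: conservation ------------------------------------------------
    ref = config.reference_species
    cons_rows: list[dict] = []
    identity_rows: list[dict] = []
    if promoters and ref in promoters and len(promoters) > 1:
        try:
            ref_by_gene = {}
            for rec in promoters[ref]:
                ref_by_gene.setdefault(_gene_variant(rec.id)[0], rec)
            for species, recs in promoters.items():
                if species == ref:
                    continue
                by_gene = {}
                for rec in recs:
                    by_gene.setdefault(_gene_variant(rec.id)[0], rec)
                for gene, ref_rec in ref_by_gene.items():
                    if gene not in by_gene:
                        continue
                    other_rec = by_gene[gene]
                    aln = _load_or_build_alignment(
                        config, gene, ref, species, ref_rec, other_rec
                    )
                    profile = conservation.identity_profile(
                        aln, pair=(ref, species), window=config.cons_window
                    )
                    regions = conservation.call_conserved_regions(
                        profile, config.cons_min_identity, config.cons_min_len
                    )
                    identity_rows.append(
                        {
                            "gene": gene,
                            "species": species,
                            "pairwise_identity_pct": round(
                                conservation.pairwise_identity(aln, (ref, species)), 2
                            ),
                            "n_conserved_regions": len(regions),
                            "conserved_cols": sum(e - s for s, e in regions),
                        }
                    )
                    chits = conservation.conserved_hits(
                        {
                            ref: hits_by_record[(ref, ref_rec.id)],
                            species: hits_by_record[(species, other_rec.id)],
                        },
                        aln,
                        regions,
                        min_col_overlap=config.cons_min_col_overlap,
                        reference=ref,
                    )
                    for row in conservation.conserved_hits_to_rows(chits):
                        row["gene"] = gene
                        cons_rows.append(row)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("conservation", str(exc)) from exc
        pd.DataFrame(cons_rows).to_csv(outdir / "conserved_hits.tsv", sep="\t", index=False)
        pd.DataFrame(identity_rows).to_csv(
            outdir / "conservation_summary.tsv", sep="\t", index=False
        )
        outputs["conserved_hits"] = outdir / "conserved_hits.tsv"
        note(f"conservation: {len(cons_rows)} conserved hit pairs")

    # --- stage: count tables ------------------------------------------------
    if promoters:
        try:
            rows = []
            groups_json = {}
            for (species, rec_id), rec_hits in sorted(hits_by_record.items()):
                gene, variant = _gene_variant(rec_id)
                row = summarize.count_by_family(
                    rec_hits, family_map, config.members_of_interest
                )
                row.update({"gene": gene, "species": species, "variant": variant})
                rows.append(row)
                groups = summarize.find_overlaps(rec_hits)
                if groups:
                    groups_json[f"{species}:{rec_id}"] = summarize.overlap_groups_to_json(
                        groups
                    )
            table = summarize.build_dataset_table(rows)
            table.to_csv(outdir / "count_table.tsv", sep="\t", index=False)
            (outdir / "overlap_groups.json").write_text(json.dumps(groups_json, indent=2))
            outputs["count_table"] = table
        except Exception as exc:
            raise PipelineError("summarize", str(exc)) from exc
        note(f"count table: {len(table)} promoter rows")

        # Table-2-style composition report for the reference species
        comp_rows = []
        for rec in promoters.get(ref, []):
            rec_hits = hits_by_record[(ref, rec.id)]
            comp_rows.append(
                {
                    "gene": _gene_variant(rec.id)[0],
                    "variant": _gene_variant(rec.id)[1],
                    "gc_percent": round(100 * seqio.gc_content(rec.seq), 2),
                    **{
                        f"{tf}_distinct": len(
                            {(h.start, h.end) for h in rec_hits if h.tf_name == tf}
                        )
                        for tf in config.background_tfs
                    },
                    **{
                        f"{tf}_raw": sum(1 for h in rec_hits if h.tf_name == tf)
                        for tf in config.background_tfs
                    },
                }
            )
        pd.DataFrame(comp_rows).to_csv(outdir / "composition.tsv", sep="\t", index=False)

    # --- stage: 3'UTR ARE ---------------------------------------------------
    if config.utr3:
        try:
            utrs = seqio.read_fasta(config.utr3, role="utr3")
            summaries = [are_utr.utr_summary(u, config.are_params) for u in utrs]
            pd.DataFrame(are_utr.summaries_to_rows(summaries)).to_csv(
                outdir / "utr_summary.tsv", sep="\t", index=False
            )
            site_rows = []
            for u in utrs:
                for s in are_utr.classify_are(u.seq, config.are_params, seq_id=u.id):
                    site_rows.append(
                        (u.id, s.interval.start, s.interval.end,
                         f"ARE_class_{s.are_class}", 1.0, "+")
                    )
            seqio.write_bed6(site_rows, outdir / "are_sites.bed")
            outputs["utr_summary"] = outdir / "utr_summary.tsv"
        except Exception as exc:
            raise PipelineError("are", str(exc)) from exc
        note(f"ARE: {len(utrs)} UTRs classified")

    # --- stage: background --------------------------------------------------
    if config.background_n > 0 and promoters.get(ref):
        try:
            pwm_by_name = {p.tf_name: p for p in pwms}
            comparisons = []
            for tf in config.background_tfs:
                if tf not in pwm_by_name:
                    note(f"background: matrix {tf} not loaded, skipped")
                    continue
                comparisons.append(
                    background.specificity_comparison(
                        pwm_by_name[tf],
                        promoters[ref],
                        n_rand=config.background_n,
                        length=config.background_length,
                        composition=config.background_composition,
                        rel_threshold=config.rel_threshold,
                        seed=config.background_seed,
                    )
                )
            pd.DataFrame(background.comparisons_to_rows(comparisons)).to_csv(
                outdir / "background.tsv", sep="\t", index=False
            )
            outputs["background"] = outdir / "background.tsv"
        except Exception as exc:
            raise PipelineError("background", str(exc)) from exc
        note(f"background: {config.background_n} random sequences of "
             f"{config.background_length} bp, seed {config.background_seed}")
    elif config.background_n == 0:
        note("background: n=0, stage skipped")

    # --- stage: ChIP-seq support -------------------------------------------
    if config.peaks and promoters.get(ref):
        try:
            peak_sets = {
                cl: chipseq_xref.read_peaks(path, cell_line=cl)
                for cl, path in config.peaks.items()
            }
            ref_hits = [
                h for rec in promoters[ref] for h in hits_by_record[(ref, rec.id)]
            ]
            lengths = {rec.id: len(rec.seq) for rec in promoters[ref]}
            report = chipseq_xref.support_summary(
                ref_hits, peak_sets, promoter_lengths=lengths
            )
            pd.DataFrame(chipseq_xref.support_to_rows(report)).to_csv(
                outdir / "chipseq_support.tsv", sep="\t", index=False
            )
            pd.DataFrame(
                [{"seq_id": k, "fraction_lines_with_peak": v}
                 for k, v in sorted(report.per_promoter.items())]
            ).to_csv(outdir / "chipseq_promoter_support.tsv", sep="\t", index=False)
            outputs["chipseq_support"] = outdir / "chipseq_support.tsv"
        except Exception as exc:
            raise PipelineError("chipseq", str(exc)) from exc
        note(f"chipseq: {len(peak_sets)} cell lines cross-referenced")

    (outdir / "run_log.txt").write_text("\n".join(log) + "\n")
    outputs["log"] = outdir / "run_log.txt"
    return outputs


def _config_dict(config: PipelineConfig) -> dict:
    d = asdict(config)
    d["are_params"] = asdict(config.are_params)
    return d


def _load_or_build_alignment(config, gene, ref, species, ref_rec, other_rec):
    if config.alignment_dir:
        path = Path(config.alignment_dir) / f"{gene}_{ref}_{species}.aln"
        if path.exists():
            aln = conservation.parse_alignment(path, fmt="clustal")
            labels = set(aln.species())
            if not {ref, species} <= labels:
                raise PipelineError(
                    "conservation",
                    f"alignment {path} lacks rows for {ref}/{species}",
                )
            return aln
    aln = conservation.align_pair(
        ref_rec.seq,
        other_rec.seq,
        match=config.align_match,
        mismatch=config.align_mismatch,
        gap=config.align_gap,
        label_a=ref,
        label_b=species,
    )
    return aln
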