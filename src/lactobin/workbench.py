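"""End-to-end orchestration: configuration, logging, and the staged
amplicon -> enrichment -> binning -> census -> pathway replay.

``run_pipeline`` chains whichever stages the supplied inputs enable and
writes a single JSON report carrying every intermediate count (reads in/out
per filter, OTUs, enrichment calls, contigs selected, assembly statistics,
marker census, pathway completeness).  The configuration is serialized
verbatim into the output directory so every number in the report is
reproducible from persisted state; all randomness flows from the single
config seed through named per-stage substreams.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Any

import pandas as pd

from . import amplicon, binning, markers, pathways
from .seqio import (SampleDesign, SeqRecord, read_design, read_fasta,
                    read_fastq, write_fasta)

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All stage parameters; defaults are the study's printed values."""

    out_dir: str = "lactobin_out"
    seed: int = 0

    # amplicon stage
    reads_dir: str | None = None        # {sample_id}_R1.fastq / _R2.fastq
    design: str | None = None
    fwd_primer: str | None = None
    rev_primer: str | None = None
    radius: float = 0.04
    min_len: int = 400
    max_len: int = 580
    min_mean_q: float = 33.0
    min_overlap: int = 20
    max_mismatch_frac: float = 0.1
    enrich_day: int = 14
    min_fold: float = 5.0

    # binning stage
    contigs: str | None = None
    ref_proteome: str | None = None
    shotgun_min_len: int = 200
    id_min_pct: float = 50.0
    cov_min_pct: float = 70.0
    min_hits: int = 1

    # validation / profiling stages
    ref_16s: str | None = None
    marker_fasta: str | None = None
    annotations: str | None = None

    log_level: str = "INFO"

    def validate(self) -> None:
        if self.max_len < self.min_len:
            raise ValueError("max_len < min_len")
        if not (0 < self.radius < 0.5):
            raise ValueError("radius must be in (0, 0.5)")
        if self.reads_dir and not (self.design and self.fwd_primer and self.rev_primer):
            raise ValueError("amplicon stage needs design and both primers")

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        import tomllib

        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute every stage the config's inputs enable; returns the report."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(json.dumps(asdict(config), indent=2))
    logging.basicConfig(level=config.log_level)
    report: dict[str, Any] = {"stages": []}

    otus: list[amplicon.Otu] = []
    selected: list[SeqRecord] = []
    try:
        if config.reads_dir:
            report["amplicon"] = _amplicon_stage(config, out)
            report["stages"].append("amplicon")
            otus = report["amplicon"].pop("_otus")
        if config.contigs and config.ref_proteome:
            report["binning"] = _binning_stage(config, out)
            report["stages"].append("binning")
            selected = report["binning"].pop("_selected")
        if config.marker_fasta and selected:
            report["census"] = _census_stage(config, selected)
            report["stages"].append("census")
        if config.ref_16s and selected:
            report["rrna"] = _rrna_stage(config, selected, out)
            report["stages"].append("rrna")
        if config.annotations:
            report["pathways"] = _pathway_stage(config, out)
            report["stages"].append("pathways")
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        stage = report["stages"][-1] if report["stages"] else "setup"
        raise StageError(stage, exc) from exc

    (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
    return report


def _amplicon_stage(config: RunConfig, out: Path) -> dict[str, Any]:
    design = read_design(config.design)
    params = amplicon.ScreenParams(config.fwd_primer, config.rev_primer,
                                   config.min_len, config.max_len, config.min_mean_q)
    reads_dir = Path(config.reads_dir)
    screened: list[tuple[SeqRecord, str]] = []
    counts = {"pairs_in": 0, "merged": 0, "fail_primer": 0, "fail_length": 0,
              "fail_quality": 0, "screened": 0}
    for d in design:
        r1 = reads_dir / f"{d.sample_id}_R1.fastq"
        r2 = reads_dir / f"{d.sample_id}_R2.fastq"
        if not r1.exists():
            continue
        for fwd, rev in zip(read_fastq(r1), read_fastq(r2)):
            counts["pairs_in"] += 1
            merged = amplicon.merge_read_pair(fwd, rev, config.min_overlap,
                                              config.max_mismatch_frac)
            if merged is None:
                continue
            counts["merged"] += 1
            res = amplicon.screen_read(merged, params)
            if not res.passed:
                counts[f"fail_{res.reason}"] += 1
                continue
            counts["screened"] += 1
            screened.append((res.record, d.sample_id))
    log.info("amplicon screen: %s", counts)

    uniques = amplicon.dereplicate(screened)
    clustered = amplicon.cluster_otus(uniques, radius=config.radius)
    kept, removed = amplicon.remove_chimeras(clustered)
    counts["uniques"] = len(uniques)
    counts["otus_clustered"] = len(clustered)
    counts["otus_chimeric"] = len(removed)
    counts["reads_in_chimeric_otus"] = sum(o.total_count for o in removed)
    counts["reads_in_otus"] = sum(o.total_count for o in kept)

    table = amplicon.build_count_table(kept, design)
    write_fasta([o.centroid for o in kept], out / "otus.fasta")
    table.to_tsv(out / "otu_table.tsv")

    calls = amplicon.detect_enriched_otus(table, design, config.enrich_day,
                                          config.min_fold)
    pd.DataFrame([{
        "otu_id": c.otu_id, "donor": c.donor, "control": c.control_abundance,
        "supplemented": ";".join(f"{x:.6g}" for x in c.supplemented_abundances),
        "max_fold_change": c.max_fold_change, "enriched": c.enriched,
    } for c in calls]).to_csv(out / "enrichment.tsv", sep="\t", index=False)

    venn = None
    donors = sorted({d.donor for d in design})
    if len(donors) == 2:
        cols = {don: [d.sample_id for d in design if d.donor == don] for don in donors}
        ta = amplicon.CountTable(table.counts[cols[donors[0]]])
        tb = amplicon.CountTable(table.counts[cols[donors[1]]])
        drop = lambda t: t.counts.index[t.counts.sum(axis=1) > 0]  # noqa: E731
        ta = amplicon.CountTable(ta.counts.loc[drop(ta)])
        tb = amplicon.CountTable(tb.counts.loc[drop(tb)])
        cmp = amplicon.compare_communities(ta, tb)
        venn = dataclasses.asdict(cmp)
        pd.DataFrame([{"donor_a": donors[0], "donor_b": donors[1], **venn}]).to_csv(
            out / "venn.tsv", sep="\t", index=False)

    taxonomy = []
    if config.ref_16s:
        refs = read_fasta(config.ref_16s)
        taxonomy = [dataclasses.asdict(amplicon.assign_taxonomy(o, refs)) for o in kept]
        pd.DataFrame(taxonomy).to_csv(out / "taxonomy.tsv", sep="\t", index=False)

    return {
        "filter_counts": counts,
        "n_otus": len(kept),
        "enriched": [dataclasses.asdict(c) for c in calls if c.enriched],
        "taxonomy": taxonomy,
        "venn": venn,
        "_otus": kept,
    }


def _binning_stage(config: RunConfig, out: Path) -> dict[str, Any]:
    contigs = binning.filter_shotgun_reads(read_fasta(config.contigs),
                                           config.shotgun_min_len)
    refs = read_fasta(config.ref_proteome)
    result = binning.screen_contigs(contigs, refs, config.id_min_pct,
                                    config.cov_min_pct, config.min_hits)
    selected = [c for c in contigs if c.id in set(result.selected_contig_ids)]
    write_fasta(selected, out / "selected_contigs.fasta")
    rows = [dataclasses.asdict(h) for hits in result.hits.values() for h in hits]
    pd.DataFrame(rows, columns=["query_id", "ref_id", "aln_len", "identity_pct",
                                "coverage_pct", "score"]
                 ).to_csv(out / "hits.tsv", sep="\t", index=False)
    stats = dataclasses.asdict(result.stats) if result.stats else None
    (out / "stats.json").write_text(json.dumps({
        "input": dataclasses.asdict(binning.assembly_stats(contigs)) if contigs else None,
        "selected": stats,
    }, indent=2))
    log.info("binning: %d/%d contigs selected", len(selected), len(contigs))
    return {
        "n_contigs_in": len(contigs),
        "n_selected": len(selected),
        "stats": stats,
        "_selected": selected,
    }


def _bin_proteins(selected: list[SeqRecord]) -> list[str]:
    return [cds.aa_seq for contig in selected for cds in binning.call_orfs(contig)]


def _census_stage(config: RunConfig, selected: list[SeqRecord]) -> dict[str, Any]:
    refs, panel = markers.read_marker_fasta(config.marker_fasta)
    census = markers.rprotein_census(_bin_proteins(selected), refs, panel=panel)
    log.info("census: %s", census.summary)
    return dataclasses.asdict(census)


def _rrna_stage(config: RunConfig, selected: list[SeqRecord], out: Path) -> dict[str, Any]:
    refs = read_fasta(config.ref_16s)
    hits = markers.find_16s(selected, refs)
    pd.DataFrame([dataclasses.asdict(h) for h in hits]).to_csv(
        out / "rrna.tsv", sep="\t", index=False)
    return {"n_hits": len(hits), "hits": [dataclasses.asdict(h) for h in hits]}


def _pathway_stage(config: RunConfig, out: Path) -> dict[str, Any]:
    ann = pathways.read_annotations(config.annotations)
    calls = [pathways.evaluate_pathway(ann, t) for t in pathways.builtin_templates()]
    products = pathways.end_product_report(ann)
    panels = [pathways.evaluate_pathway(ann, t) for t in pathways.builtin_panels()]
    rows = [dataclasses.asdict(c) for c in calls + panels]
    rows += [{"product": p, **dataclasses.asdict(c)} for p, c in products.items()]
    pd.DataFrame(rows).to_csv(out / "pathway_report.tsv", sep="\t", index=False)
    return {
        "pathways": {c.pathway: c.completeness for c in calls},
        "complete": [c.pathway for c in calls if c.complete],
        "end_products": {p: c.complete for p, c in products.items()},
        "panels": {c.pathway: c.completeness for c in panels},
    }
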