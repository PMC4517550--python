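"""End-to-end pipelines tying the stages together, plus run configuration.

``run_simulation`` materialises the synthetic universe (locus FASTA + GTF,
paired SAM, truth table, simulated Ct table).  ``run_demo`` runs the whole
analysis on it — filtering, depth, unique/shared partitioning, naive vs
unique-region quantification, bleed-through, and ΔΔCt qPCR — and writes a
report directory.  Every output file carries a header comment with the
package version, seed and key parameters.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .annotation import contributing_transcripts_report, partition_unique_shared, write_gtf
from .coverage import (
    AlignmentFilter,
    compute_depth,
    filter_alignments,
    region_summary,
    write_bedgraph,
)
from .locus import (
    FUSION_TID,
    INS_TID,
    build_default_locus,
    sam_header,
    simulate_ct,
    simulate_reads,
    write_fasta,
    write_sam,
    write_truth,
)
from .qpcr import qpcr_summary, write_ct_table
from .quantify import quantify_locus

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Parameters of a simulation/demo run; serialisable as key=value text."""

    seed: int = 1
    n_fragments: int = 200_000
    frag_len_mean: float = 300.0
    frag_len_sd: float = 30.0
    read_len: int = 75
    min_mapq: int = 10
    max_insert: int = 500_000
    cap: int | None = None
    reference_gene: str = "GAPDH"
    reference_transcript: str = "INS"
    averaging: str = "geometric"
    ct_efficiency: float = 1.0
    ct_intercept: float = 38.0
    ct_noise_sd: float = 0.5
    ct_max_cycles: float = 40.0
    ct_n_preps: int = 3
    abundances: dict[str, float] = field(default_factory=dict)

    def alignment_filter(self) -> AlignmentFilter:
        return AlignmentFilter(min_mapq=self.min_mapq, max_insert=self.max_insert)

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# fusionbleed {__version__} run configuration\n")
            for f in dataclasses.fields(self):
                value = getattr(self, f.name)
                if f.name == "abundances":
                    value = ",".join(f"{k}:{v:g}" for k, v in value.items())
                elif value is None:
                    value = "none"
                fh.write(f"{f.name} = {value}\n")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        raw: dict[str, str] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                if "=" not in line:
                    raise ValueError(f"bad config line: {line!r}")
                key, value = (p.strip() for p in line.split("=", 1))
                raw[key] = value
        kwargs: dict = {}
        for f in dataclasses.fields(cls):
            if f.name not in raw:
                continue
            v = raw[f.name]
            if f.name == "abundances":
                kwargs[f.name] = (
                    {}
                    if not v
                    else {k: float(x) for k, x in (pair.split(":") for pair in v.split(","))}
                )
            elif f.name == "cap":
                kwargs[f.name] = None if v == "none" else int(v)
            elif f.type in ("int",):
                kwargs[f.name] = int(v)
            elif f.type in ("float",):
                kwargs[f.name] = float(v)
            else:
                kwargs[f.name] = v
        return cls(**kwargs)


def _header_lines(config: RunConfig, stage: str) -> list[str]:
    return [
        f"fusionbleed {__version__} {stage}",
        f"seed={config.seed} n_fragments={config.n_fragments} "
        f"frag_len_mean={config.frag_len_mean:g} frag_len_sd={config.frag_len_sd:g} "
        f"read_len={config.read_len} min_mapq={config.min_mapq} "
        f"max_insert={config.max_insert} cap={config.cap}",
    ]


def _write_tsv(df: pd.DataFrame, path, config: RunConfig, stage: str) -> None:
    with open(path, "w") as fh:
        for line in _header_lines(config, stage):
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


def _build_universe(config: RunConfig):
    spec = build_default_locus(config.seed)
    if config.abundances:
        spec.abundances.update(config.abundances)
    records, truth = simulate_reads(
        spec,
        n_fragments=config.n_fragments,
        frag_len_mean=config.frag_len_mean,
        frag_len_sd=config.frag_len_sd,
        read_len=config.read_len,
        seed=config.seed,
    )
    return spec, records, truth


def _gene_abundances(spec) -> dict[str, float]:
    """Gene-level abundances for the Ct simulator; the reference gene is set
    to a mid-range abundance typical of a housekeeping control."""
    by_gene = {
        "INS": spec.abundances[INS_TID],
        "INS-IGF2": spec.abundances[FUSION_TID],
        "IGF2": spec.abundances["IGF2-like-001"],
        "GAPDH": 1000.0,
    }
    return by_gene


def artefact_replicates(
    n_fragments: int = 200_000,
    seeds: tuple[int, ...] = tuple(range(1, 11)),
    frag_len_mean: float = 300.0,
    frag_len_sd: float = 30.0,
    read_len: int = 75,
) -> pd.DataFrame:
    """Replicate the artefact experiment across seeds on the default locus.

    For each seed, simulates ``n_fragments`` fragments at the default
    20,000 : 1 abundance ratio, applies the default alignment filter and
    quantifies with both estimators.  Returns one row per seed with the
    naive and unique-region expressions of the short gene and the fusion,
    the fusion's unique fragment count and its bleed-through index.
    """
    rows = []
    for seed in seeds:
        spec = build_default_locus(seed)
        records, _truth = simulate_reads(
            spec,
            n_fragments=n_fragments,
            frag_len_mean=frag_len_mean,
            frag_len_sd=frag_len_sd,
            read_len=read_len,
            seed=seed,
            with_sequence=False,
        )
        filtered = filter_alignments(records, AlignmentFilter())
        quant = quantify_locus(filtered, spec.annotation()).set_index("transcript_id")
        rows.append(
            {
                "seed": seed,
                "naive_ins": quant.loc[INS_TID, "naive_expression"],
                "naive_fusion": quant.loc[FUSION_TID, "naive_expression"],
                "unique_ins": quant.loc[INS_TID, "unique_expression"],
                "unique_fusion": quant.loc[FUSION_TID, "unique_expression"],
                "unique_fusion_fragments": quant.loc[FUSION_TID, "unique_fragments"],
                "fusion_bleedthrough": quant.loc[FUSION_TID, "bleedthrough_index"],
            }
        )
    return pd.DataFrame(rows)


def run_simulation(config: RunConfig, out_dir) -> dict[str, Path]:
    """Write the synthetic universe to ``out_dir``; deterministic per seed."""
    if config.n_fragments <= 0:
        raise ValueError("n_fragments must be > 0")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec, records, truth = _build_universe(config)
    paths = {
        "fasta": out / "locus.fa",
        "gtf": out / "locus.gtf",
        "sam": out / "reads.sam",
        "truth": out / "truth.tsv",
        "ct": out / "ct.tsv",
        "config": out / "run_config.txt",
    }
    write_fasta(spec, paths["fasta"], seed=config.seed)
    write_gtf(spec.annotation(), paths["gtf"])
    write_sam(records, sam_header(spec, seed=config.seed), str(paths["sam"]))
    write_truth(truth, paths["truth"], comment=" ".join(_header_lines(config, "truth")))
    ct = simulate_ct(
        _gene_abundances(spec),
        efficiency=config.ct_efficiency,
        intercept_ct=config.ct_intercept,
        noise_sd=config.ct_noise_sd,
        max_cycles=config.ct_max_cycles,
        n_preps=config.ct_n_preps,
        seed=config.seed,
    )
    write_ct_table(ct, paths["ct"], comments=_header_lines(config, "simulated Ct"))
    config.to_file(paths["config"])
    return paths


def run_demo(config: RunConfig, out_dir) -> dict:
    """Self-contained demonstration: simulate, analyse, report.

    Writes depth.bedgraph, region_summary.tsv, quantification.tsv,
    qpcr.tsv, contributing_transcripts.tsv and summary.txt; returns the
    in-memory results keyed by the same names.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec, records, truth = _build_universe(config)
    ann = spec.annotation()

    filtered = filter_alignments(records, config.alignment_filter())
    track = compute_depth(filtered, spec.window, cap=config.cap)
    write_bedgraph(track, out / "depth.bedgraph", extra_comments=_header_lines(config, "depth"))

    fusion_part = partition_unique_shared(ann.transcript(FUSION_TID), ann)
    summary = region_summary(track, fusion_part)
    _write_tsv(summary, out / "region_summary.tsv", config, "fusion region summary")

    quant = quantify_locus(filtered, ann)
    _write_tsv(quant, out / "quantification.tsv", config, "quantification")

    ct = simulate_ct(
        _gene_abundances(spec),
        efficiency=config.ct_efficiency,
        intercept_ct=config.ct_intercept,
        noise_sd=config.ct_noise_sd,
        max_cycles=config.ct_max_cycles,
        n_preps=config.ct_n_preps,
        seed=config.seed,
    )
    qtable = qpcr_summary(
        ct,
        reference_gene=config.reference_gene,
        reference_transcript=config.reference_transcript,
        averaging=config.averaging,
    )
    _write_tsv(qtable, out / "qpcr.tsv", config, "qPCR summary")

    report = contributing_transcripts_report(ann)
    _write_tsv(report, out / "contributing_transcripts.tsv", config, "contributing transcripts")

    qrow = quant.set_index("transcript_id")
    naive_fus = qrow.loc[FUSION_TID, "naive_expression"]
    naive_ins = qrow.loc[INS_TID, "naive_expression"]
    uniq_fus = qrow.loc[FUSION_TID, "unique_expression"]
    uniq_ins = qrow.loc[INS_TID, "unique_expression"]
    bleed = qrow.loc[FUSION_TID, "bleedthrough_index"]
    lines = _header_lines(config, "demo summary") + [
        "",
        f"naive expression (frags/kb): {INS_TID}={naive_ins:.1f} {FUSION_TID}={naive_fus:.1f} "
        f"(apparent gap {naive_ins / naive_fus:.1f}x)" if naive_fus else
        f"naive expression (frags/kb): {INS_TID}={naive_ins:.1f} {FUSION_TID}={naive_fus:.1f}",
        f"unique-region expression (frags/kb): {INS_TID}={uniq_ins:.1f} {FUSION_TID}={uniq_fus:.3f}",
        (
            f"unique-region abundance ratio estimate: "
            f"{uniq_ins / uniq_fus:,.0f}x (truth "
            f"{spec.abundances[INS_TID] / spec.abundances[FUSION_TID]:,.0f}x)"
            if uniq_fus
            else "unique-region estimate undefined (no fragments in unique segments)"
        ),
        f"fusion bleed-through index: {bleed:.4f}",
    ]
    (out / "summary.txt").write_text("\n".join(lines) + "\n")
    return {
        "spec": spec,
        "truth": truth,
        "track": track,
        "region_summary": summary,
        "quantification": quant,
        "qpcr": qtable,
        "contributing": report,
        "summary_lines": lines,
    }
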