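"""Relative qPCR quantification (ΔΔCt) with missing-Ct support.

The workflow mirrors standard SYBR-green relative quantification: technical
duplicates are averaged per preparation, Ct values are normalised against a
reference gene (ΔCt), and expression relative to a reference transcript is
computed as 2^(−ΔΔCt) with the ΔΔCt averaged over preparations before
exponentiation (geometric-mean convention; the reference-gene term cancels
within a preparation).  Failed amplification ("No Ct") is handled by
pairwise-complete exclusion — a preparation contributes only when both
members of a difference are present — and is never imputed.

Amplification efficiency is taken as 100% (one cycle = one doubling).
"""

from __future__ import annotations

import math
from importlib import resources
from typing import Iterable

import numpy as np
import pandas as pd

CT_COLUMNS = ["sample", "gene", "prep", "replicate", "ct"]
NO_CT = "NoCt"


class UndefinedExpressionError(ValueError):
    """No preparation has both Ct values needed for a ratio."""


def validate_ct_table(t: pd.DataFrame) -> None:
    missing = [c for c in CT_COLUMNS if c not in t.columns]
    if missing:
        raise ValueError(f"Ct table lacks columns: {missing}")
    if t.duplicated(subset=["sample", "gene", "prep", "replicate"]).any():
        raise ValueError("duplicate (sample, gene, prep, replicate) rows")
    present = t["ct"].dropna()
    if (present <= 0).any():
        raise ValueError("Ct values must be positive when present")


def read_ct_table(path) -> pd.DataFrame:
    """TSV reader; missing Ct encoded as ``NoCt``; '#' lines are comments."""
    t = pd.read_csv(path, sep="\t", comment="#", dtype={"sample": str, "gene": str})
    if "ct" in t.columns:
        t["ct"] = pd.to_numeric(t["ct"].replace(NO_CT, np.nan), errors="raise")
    validate_ct_table(t)
    return t


def write_ct_table(t: pd.DataFrame, path, comments: Iterable[str] = ()) -> None:
    validate_ct_table(t)
    out = t.copy()
    out["ct"] = out["ct"].map(lambda v: NO_CT if pd.isna(v) else f"{v:g}")
    with open(path, "w") as fh:
        for c in comments:
            fh.write(f"# {c}\n")
        out.to_csv(fh, sep="\t", index=False)


def load_packaged_ct_table() -> pd.DataFrame:
    """The published per-preparation Ct values shipped with the package."""
    ref = resources.files("fusionbleed.data") / "published_ct.tsv"
    with resources.as_file(ref) as path:
        return read_ct_table(path)


def prep_means(t: pd.DataFrame) -> pd.DataFrame:
    """Average technical replicates per preparation.

    Returns columns (sample, gene, prep, ct); a preparation's mean is NaN
    only when all its replicates are missing.
    """
    validate_ct_table(t)
    out = (
        t.groupby(["sample", "gene", "prep"], sort=True)["ct"]
        .mean()  # skips NaN; all-NaN groups yield NaN
        .reset_index()
    )
    return out


def gapdh_normalize(pm: pd.DataFrame, reference_gene: str = "GAPDH") -> pd.DataFrame:
    """Mean ΔCt per (sample, gene) against a reference gene.

    ΔCt is computed per preparation (ct_gene − ct_reference) and averaged
    over preparations where both are present.  A sample without any
    reference-gene measurement raises ``ValueError``.
    """
    rows = []
    for sample, sub in pm.groupby("sample", sort=True):
        ref = sub[sub["gene"] == reference_gene].set_index("prep")["ct"]
        if ref.dropna().empty:
            raise ValueError(f"reference gene {reference_gene!r} missing for sample {sample!r}")
        for gene, gsub in sub.groupby("gene", sort=True):
            cts = gsub.set_index("prep")["ct"]
            deltas = (cts - ref).dropna()
            rows.append(
                {
                    "sample": sample,
                    "gene": gene,
                    "delta_ct": float(deltas.mean()) if len(deltas) else np.nan,
                    "n_preps": int(len(deltas)),
                }
            )
    return pd.DataFrame(rows, columns=["sample", "gene", "delta_ct", "n_preps"])


def relative_expression(
    pm: pd.DataFrame,
    target: str,
    reference_transcript: str,
    sample: str,
    averaging: str = "geometric",
) -> float:
    """Expression of ``target`` relative to ``reference_transcript`` in a sample.

    Per preparation with both Cts present, ΔΔCt = ct(target) − ct(reference);
    ``geometric`` (default) returns 2^(−mean ΔΔCt), ``arithmetic`` the mean of
    per-prep 2^(−ΔΔCt).  The input-control term cancels within a preparation,
    so prep means can be used directly.  Raises
    :class:`UndefinedExpressionError` when no preparation is complete.
    """
    sub = pm[pm["sample"] == sample]
    tgt = sub[sub["gene"] == target].set_index("prep")["ct"]
    ref = sub[sub["gene"] == reference_transcript].set_index("prep")["ct"]
    if tgt.empty or ref.empty:
        raise KeyError(f"target or reference not measured in sample {sample!r}")
    ddct = (tgt - ref).dropna()
    if ddct.empty:
        raise UndefinedExpressionError(
            f"no preparation with both {target!r} and {reference_transcript!r} in {sample!r}"
        )
    if averaging == "geometric":
        return float(2.0 ** (-ddct.mean()))
    if averaging == "arithmetic":
        return float((2.0 ** (-ddct)).mean())
    raise ValueError(f"averaging must be 'geometric' or 'arithmetic', got {averaging!r}")


def fold_difference(rel: float) -> float:
    """Fold difference of the reference over the target (1 / relative expression)."""
    if rel <= 0:
        raise ValueError(f"relative expression must be > 0, got {rel}")
    return 1.0 / rel


def round_sigfig(x: float, n: int = 1) -> float:
    """Round to n significant figures (display helper for fold differences)."""
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + (n - 1))


def format_relative(rel: float) -> str:
    """Render a relative expression at 6 decimal places, the precision at
    which all the published ratios this package reproduces are printed."""
    return f"{rel:.6f}"


def qpcr_summary(
    t: pd.DataFrame,
    reference_gene: str = "GAPDH",
    reference_transcript: str = "INS",
    averaging: str = "geometric",
) -> pd.DataFrame:
    """Per (sample, gene) summary: mean Ct, ΔCt and expression relative to a
    reference transcript — the package's analogue of a published qPCR table."""
    pm = prep_means(t)
    norm = gapdh_normalize(pm, reference_gene=reference_gene)
    rows = []
    for (sample, gene), _ in norm.set_index(["sample", "gene"]).iterrows():
        sub = pm[(pm["sample"] == sample) & (pm["gene"] == gene)]["ct"].dropna()
        try:
            rel = relative_expression(
                pm, gene, reference_transcript, sample, averaging=averaging
            )
        except (UndefinedExpressionError, KeyError):
            rel = np.nan
        delta = norm[(norm["sample"] == sample) & (norm["gene"] == gene)]["delta_ct"].iloc[0]
        rows.append(
            {
                "sample": sample,
                "gene": gene,
                "mean_ct": float(sub.mean()) if len(sub) else np.nan,
                "delta_ct": delta,
                "rel_to_reference": rel,
            }
        )
    return pd.DataFrame(rows, columns=["sample", "gene", "mean_ct", "delta_ct", "rel_to_reference"])
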