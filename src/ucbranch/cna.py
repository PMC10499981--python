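"""Arm-level copy-number burden and downstream group/cis-effect screens.

Arm burden aggregates segment log2 copy-ratios over a chromosome arm with
length weighting.  The default is the length-weighted MEAN so the value
stays on the log2-ratio scale and remains comparable to the +/-1
amplification/deletion cutoff; the literal length-weighted sum is exposed
as an option.  Coordinates are 0-based half-open throughout; SEG input is
assumed 1-based inclusive and converted on read.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from . import stats as _stats

__all__ = [
    "CALL_CUTOFF",
    "arm_burden",
    "call_amp_del",
    "call_matrix",
    "group_freq_test",
    "cis_effect",
    "cis_effect_screen",
    "read_seg_tsv",
    "write_seg_tsv",
    "read_arms_tsv",
]

CALL_CUTOFF = 1.0  # |log2 ratio| >= 1 defines amplification / deletion

#: GISTIC2 parameter block of the upstream pipeline, recorded as metadata
GISTIC_PARAMS = "-ta 0.1 -tb 0.1 -brlen 0.98 -conf 0.9"

SEG_COLUMNS = ["sample", "chrom", "start", "end", "log2_ratio"]


def _validate_segments(segments: pd.DataFrame) -> pd.DataFrame:
    missing = set(SEG_COLUMNS) - set(segments.columns)
    if missing:
        raise ValueError(f"segment table missing columns: {sorted(missing)}")
    if (segments["end"] <= segments["start"]).any():
        raise ValueError("segments must satisfy end > start")
    return segments


def arm_burden(
    segments: pd.DataFrame,
    arms: pd.DataFrame,
    mode: str = "mean",
) -> pd.DataFrame:
    """Length-weighted arm-level burden per sample.

    ``arms`` has columns arm, chrom, start, end (0-based half-open).
    burden(sample, arm) = sum_i overlap_i * log2_i / sum_i overlap_i
    (mode="mean"), or the un-normalized weighted sum (mode="sum").
    Segments spanning an arm boundary contribute only their overlapping
    part; arms with no covering segment are NaN.
    """
    if mode not in {"mean", "sum"}:
        raise ValueError("mode must be 'mean' or 'sum'")
    segments = _validate_segments(segments)
    samples = pd.unique(segments["sample"])
    out = pd.DataFrame(
        np.nan, index=pd.Index(samples, name="sample"), columns=arms["arm"].tolist()
    )
    for arm_row in arms.itertuples(index=False):
        sel = segments[segments["chrom"] == arm_row.chrom]
        if sel.empty:
            continue
        overlap = (
            np.minimum(sel["end"], arm_row.end) - np.maximum(sel["start"], arm_row.start)
        ).clip(lower=0)
        sel = sel.assign(overlap=overlap)
        sel = sel[sel["overlap"] > 0]
        if sel.empty:
            continue
        grouped = sel.groupby("sample")
        weighted = grouped.apply(
            lambda g: float((g["overlap"] * g["log2_ratio"]).sum()), include_groups=False
        )
        if mode == "mean":
            lengths = grouped["overlap"].sum()
            weighted = weighted / lengths
        out.loc[weighted.index, arm_row.arm] = weighted
    return out


def call_amp_del(value: float, cutoff: float = CALL_CUTOFF) -> str:
    """amp if value >= +cutoff, del if value <= -cutoff, else neutral.

    Comparisons are inclusive: a value exactly at the printed cutoff
    qualifies.
    """
    if not math.isfinite(value):
        raise ValueError("value must be finite")
    if value >= cutoff:
        return "amp"
    if value <= -cutoff:
        return "del"
    return "neutral"


def call_matrix(burden: pd.DataFrame, cutoff: float = CALL_CUTOFF) -> pd.DataFrame:
    """Element-wise amp/del/neutral calls; NaN burdens stay missing."""
    calls = pd.DataFrame("neutral", index=burden.index, columns=burden.columns)
    calls = calls.where(burden.notna(), other=pd.NA)
    calls[burden >= cutoff] = "amp"
    calls[burden <= -cutoff] = "del"
    return calls


def group_freq_test(calls: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    """Per-arm Fisher exact test of alteration frequency between two groups.

    ``calls`` is samples x arms with values in {amp, del, neutral} (or
    NA); a sample counts as altered on an arm when its call is amp or
    del.  Returns a per-arm table with the odds ratio, two-sided p and BH
    q-value.
    """
    groups = groups.loc[calls.index]
    levels = sorted(pd.unique(groups.dropna()))
    if len(levels) != 2:
        raise ValueError(f"need exactly two groups, got {levels}")
    g1 = groups == levels[0]
    g2 = groups == levels[1]
    rows = []
    for arm in calls.columns:
        col = calls[arm]
        altered = col.isin(["amp", "del"])
        informative = col.notna()
        a = int((altered & g1 & informative).sum())
        b = int((~altered & g1 & informative).sum())
        c = int((altered & g2 & informative).sum())
        d = int((~altered & g2 & informative).sum())
        res = _stats.fisher_exact_2x2([[a, b], [c, d]])
        rows.append({"arm": arm, "odds_ratio": res.effect, "p": res.p_value})
    table = pd.DataFrame(rows).set_index("arm")
    table["q"] = _stats.bh_adjust(table["p"].to_numpy())
    return table


def cis_effect(cna_values: pd.Series, protein: pd.Series) -> _stats.TestResult:
    """Spearman correlation of a gene's CNA value with its own protein.

    A positive rho means deletion lowers the protein (copy number and
    abundance move together).  Requires >= 5 paired observations;
    constant input yields a missing (NaN) result.
    """
    paired = pd.concat([cna_values, protein], axis=1, join="inner").dropna()
    if len(paired) < 5:
        raise ValueError("need >= 5 paired observations")
    return _stats.spearman(paired.iloc[:, 0].to_numpy(), paired.iloc[:, 1].to_numpy())


def cis_effect_screen(
    burden: pd.DataFrame,
    protein: pd.DataFrame,
    gene_to_arm: dict[str, str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Screen genes for cis-effects (rho > 0, BH-adjusted p < alpha).

    ``gene_to_arm`` maps a protein feature to the arm whose burden acts
    as its copy-number value.
    """
    rows = []
    for gene, arm in gene_to_arm.items():
        if gene not in protein.columns or arm not in burden.columns:
            continue
        try:
            res = cis_effect(burden[arm], protein[gene])
        except ValueError:
            continue
        rows.append({"gene": gene, "arm": arm, "rho": res.effect, "p": res.p_value})
    table = pd.DataFrame(rows)
    if table.empty:
        return table
    table = table.set_index("gene")
    valid = table["p"].notna()
    q = np.full(len(table), np.nan)
    q[valid.to_numpy()] = _stats.bh_adjust(table.loc[valid, "p"].to_numpy())
    table["q"] = q
    table["cis_effect"] = (table["rho"] > 0) & (table["q"] < alpha)
    return table


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_seg_tsv(path) -> pd.DataFrame:
    """Read a SEG-style TSV (1-based inclusive) into 0-based half-open."""
    seg = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(SEG_COLUMNS) - set(seg.columns)
    if missing:
        raise ValueError(f"SEG table missing columns: {sorted(missing)}")
    seg = seg.copy()
    seg["start"] = seg["start"] - 1
    return _validate_segments(seg)


def write_seg_tsv(segments: pd.DataFrame, path) -> None:
    """Write 0-based half-open segments as 1-based inclusive SEG."""
    seg = _validate_segments(segments).copy()
    seg["start"] = seg["start"] + 1
    seg[SEG_COLUMNS].to_csv(path, sep="\t", index=False)


def read_arms_tsv(path) -> pd.DataFrame:
    arms = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = {"arm", "chrom", "start", "end"} - set(arms.columns)
    if missing:
        raise ValueError(f"arm table missing columns: {sorted(missing)}")
    return arms
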