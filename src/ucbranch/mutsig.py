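"""SBS mutational-signature analysis over 96 trinucleotide contexts.

Catalog construction folds every substitution onto the pyrimidine strand
(C or T reference; purine-reference records are reverse-complemented,
flanks swapped and complemented).  De novo extraction is multiplicative-
update NMF under generalized Kullback-Leibler divergence; refitting
against a reference signature set is non-negative least squares on the
frequency-normalized catalog, with weights below 0.08 filtered out and
the remaining signatures re-fitted and renormalized.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls

__all__ = [
    "CONTEXTS_96",
    "SUBSTITUTIONS",
    "WEIGHT_THRESHOLD",
    "ExposureResult",
    "build_catalog",
    "nmf_extract",
    "refit_signatures",
    "refit_cohort",
    "assign_signature_groups",
    "validate_signature_set",
    "read_signatures_tsv",
    "write_signatures_tsv",
    "read_maf_tsv",
]

SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_BASES = "ACGT"
#: fixed category order: substitution major, then 5' flank, then 3' flank
CONTEXTS_96 = tuple(
    f"{five}[{sub}]{three}" for sub in SUBSTITUTIONS for five in _BASES for three in _BASES
)
_CONTEXT_INDEX = {c: i for i, c in enumerate(CONTEXTS_96)}
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

WEIGHT_THRESHOLD = 0.08  # refit weights below this are filtered out


def context_category(ref: str, alt: str, flank5: str, flank3: str) -> str:
    """Pyrimidine-strand context category of one substitution."""
    if ref in "AG":
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
        flank5, flank3 = _COMPLEMENT[flank3], _COMPLEMENT[flank5]
    return f"{flank5}[{ref}>{alt}]{flank3}"


def build_catalog(mutations: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Accumulate per-sample 96-context counts from a mutation table.

    Expects columns sample, ref, alt, flank5, flank3.  Indels, ambiguous
    bases and ref == alt records are skipped; the skip count is returned
    alongside the catalog (samples x 96, fixed category order).
    """
    required = {"sample", "ref", "alt", "flank5", "flank3"}
    missing = required - set(mutations.columns)
    if missing:
        raise ValueError(f"mutation table missing columns: {sorted(missing)}")
    samples = pd.unique(mutations["sample"])
    counts = pd.DataFrame(
        0, index=pd.Index(samples, name="sample"), columns=list(CONTEXTS_96), dtype=int
    )
    skipped = 0
    valid = set(_BASES)
    for row in mutations.itertuples(index=False):
        ref = str(row.ref).upper()
        alt = str(row.alt).upper()
        f5 = str(row.flank5).upper()
        f3 = str(row.flank3).upper()
        if (
            len(ref) != 1
            or len(alt) != 1
            or ref == alt
            or not {ref, alt, f5, f3} <= valid
        ):
            skipped += 1
            continue
        counts.loc[row.sample, context_category(ref, alt, f5, f3)] += 1
    return counts, skipped


# ---------------------------------------------------------------------------
# Signature sets
# ---------------------------------------------------------------------------


def validate_signature_set(signatures: pd.DataFrame) -> pd.DataFrame:
    """Check a 96 x k signature matrix: non-negative columns summing to 1."""
    if list(signatures.index) != list(CONTEXTS_96):
        if set(signatures.index) == set(CONTEXTS_96):
            signatures = signatures.loc[list(CONTEXTS_96)]
        else:
            raise ValueError("signature rows must be the 96 context categories")
    arr = signatures.to_numpy(dtype=float)
    if np.any(arr < 0):
        raise ValueError("signature probabilities must be non-negative")
    sums = arr.sum(axis=0)
    if np.any(np.abs(sums - 1.0) > 1e-9):
        raise ValueError("each signature must sum to 1 (+/- 1e-9)")
    return signatures


# ---------------------------------------------------------------------------
# De novo extraction: multiplicative-update NMF, generalized KL
# ---------------------------------------------------------------------------


def _kl_divergence(v: np.ndarray, wh: np.ndarray) -> float:
    eps = 1e-12
    mask = v > 0
    term = np.zeros_like(v)
    term[mask] = v[mask] * np.log(v[mask] / np.maximum(wh[mask], eps))
    return float((term - v + wh).sum())


def _nmf_once(v: np.ndarray, k: int, rng: np.random.Generator,
              max_iter: int, tol: float):
    eps = 1e-12
    m, n = v.shape
    w = rng.uniform(0.5, 1.5, size=(m, k)) * (v.mean() + eps)
    h = rng.uniform(0.5, 1.5, size=(k, n))
    history = [_kl_divergence(v, w @ h)]
    for _ in range(max_iter):
        wh = np.maximum(w @ h, eps)
        h *= (w.T @ (v / wh)) / np.maximum(w.sum(axis=0)[:, None], eps)
        wh = np.maximum(w @ h, eps)
        w *= ((v / wh) @ h.T) / np.maximum(h.sum(axis=1)[None, :], eps)
        obj = _kl_divergence(v, w @ h)
        history.append(obj)
        if abs(history[-2] - obj) <= tol * max(abs(history[-2]), 1.0):
            break
    return w, h, history


def nmf_extract(
    catalog: pd.DataFrame,
    k: int,
    n_restarts: int = 10,
    seed: int = 0,
    max_iter: int = 2000,
    tol: float = 1e-10,
):
    """Extract k signatures de novo from a samples x 96 catalog.

    Returns (signatures 96 x k, exposures samples x k, objective history
    of the best restart).  Signature columns are normalized to sum 1 with
    exposures rescaled accordingly; the best restart by final generalized
    KL divergence wins.
    """
    v = catalog.to_numpy(dtype=float).T  # 96 x samples
    if k < 1 or k > min(v.shape):
        raise ValueError(f"rank k={k} out of bounds for catalog shape {catalog.shape}")
    if v.sum() <= 0:
        raise ValueError("catalog is all-zero")
    seeds = np.random.SeedSequence(seed).spawn(n_restarts)
    best = None
    for ss in seeds:
        w, h, history = _nmf_once(v, k, np.random.default_rng(ss), max_iter, tol)
        if best is None or history[-1] < best[2][-1]:
            best = (w, h, history)
    w, h, history = best
    col_sums = np.maximum(w.sum(axis=0), 1e-12)
    w = w / col_sums
    h = h * col_sums[:, None]
    sig_ids = [f"DN{i + 1}" for i in range(k)]
    signatures = pd.DataFrame(w, index=list(CONTEXTS_96), columns=sig_ids)
    exposures = pd.DataFrame(h.T, index=catalog.index, columns=sig_ids)
    return signatures, exposures, history


# ---------------------------------------------------------------------------
# Refitting against a reference set
# ---------------------------------------------------------------------------


@dataclass
class ExposureResult:
    """Per-sample signature weights after thresholding and re-fit."""

    sample: str
    weights: dict[str, float]
    residual: float
    dominant: str | None
    unassigned: bool = False
    tie: bool = False


def refit_signatures(
    counts,
    reference: pd.DataFrame,
    threshold: float = WEIGHT_THRESHOLD,
    sample: str = "",
) -> ExposureResult:
    """Refit one sample's 96-context counts against reference signatures.

    NNLS on the frequency-normalized catalog, weights normalized to sum 1,
    weights below ``threshold`` removed, the remaining signatures
    re-fitted and renormalized.  If every weight falls below the threshold
    the result is flagged unassigned (not an error).
    """
    reference = validate_signature_set(reference)
    v = np.asarray(counts, dtype=float)
    if v.shape != (96,):
        raise ValueError("expected a 96-vector of context counts")
    total = v.sum()
    if total <= 0:
        raise ValueError("sample has no mutations")
    freq = v / total
    r = reference.to_numpy(dtype=float)
    w_raw, _ = nnls(r, freq)
    if w_raw.sum() <= 0:
        return ExposureResult(sample=sample, weights={}, residual=float(np.linalg.norm(freq)),
                              dominant=None, unassigned=True)
    weights = w_raw / w_raw.sum()
    keep = weights >= threshold
    if not keep.any():
        return ExposureResult(sample=sample, weights={}, residual=float(np.linalg.norm(freq)),
                              dominant=None, unassigned=True)
    w_restricted, resid = nnls(r[:, keep], freq)
    if w_restricted.sum() <= 0:
        return ExposureResult(sample=sample, weights={}, residual=float(resid),
                              dominant=None, unassigned=True)
    final = w_restricted / w_restricted.sum()
    kept_ids = reference.columns[keep]
    weight_map = {sid: float(w) for sid, w in zip(kept_ids, final)}
    top = max(weight_map.values())
    leaders = sorted(sid for sid, w in weight_map.items() if w >= top - 1e-9)
    return ExposureResult(
        sample=sample,
        weights=weight_map,
        residual=float(resid),
        dominant=leaders[0],
        tie=len(leaders) > 1,
    )


def refit_cohort(
    catalog: pd.DataFrame,
    reference: pd.DataFrame,
    threshold: float = WEIGHT_THRESHOLD,
) -> list[ExposureResult]:
    return [
        refit_signatures(catalog.loc[s].to_numpy(), reference, threshold, sample=str(s))
        for s in catalog.index
    ]


def assign_signature_groups(
    exposures: list[ExposureResult],
    histology: pd.Series | None = None,
) -> tuple[pd.Series, pd.DataFrame | None]:
    """Dominant-signature label per sample plus a stage cross-tabulation.

    Ties resolve to the lexicographically smaller signature id (flagged on
    the ExposureResult); unassigned samples are labelled "none".
    """
    labels = pd.Series(
        {r.sample: (r.dominant if not r.unassigned else "none") for r in exposures},
        name="dominant_signature",
    )
    crosstab = None
    if histology is not None:
        aligned = histology.reindex(labels.index)
        crosstab = pd.crosstab(aligned, labels)
    return labels, crosstab


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_signatures_tsv(path) -> pd.DataFrame:
    sig = pd.read_csv(path, sep="\t", index_col=0)
    return validate_signature_set(sig)


def write_signatures_tsv(signatures: pd.DataFrame, path) -> None:
    validate_signature_set(signatures).to_csv(path, sep="\t", index_label="context")


MAF_COLUMNS = ["sample", "chrom", "pos", "ref", "alt", "flank5", "flank3"]


def read_maf_tsv(path) -> pd.DataFrame:
    """MAF-like TSV with explicit flanking bases (no genome required)."""
    maf = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(MAF_COLUMNS) - set(maf.columns)
    if missing:
        raise ValueError(f"MAF table missing columns: {sorted(missing)}")
    return maf


def write_exposures_tsv(exposures: list[ExposureResult], path) -> None:
    all_sigs = sorted({sid for r in exposures for sid in r.weights})
    rows = []
    for r in exposures:
        row = {"sample": r.sample, "dominant": r.dominant or "none",
               "residual": r.residual, "unassigned": int(r.unassigned)}
        for sid in all_sigs:
            row[sid] = r.weights.get(sid, 0.0)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
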