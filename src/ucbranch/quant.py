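"""Label-free quantification chain.

From peptide evidence (XIC areas per run) to a normalized protein matrix:
in-silico tryptic digestion to count observable peptides, iBAQ (summed
peptide intensity over observable-peptide count), FOT normalization
(iBAQ over total iBAQ, x1E5, floored at 1E-5), retention-time regression
for match-between-runs transfer, and detection filtering with floor
imputation followed by log2 transform.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PEPTIDE_MIN_LEN",
    "PEPTIDE_MAX_LEN",
    "FOT_SCALE",
    "FOT_FLOOR",
    "AbundanceMatrix",
    "RtModel",
    "digest_tryptic",
    "count_observable_peptides",
    "compute_ibaq",
    "ibaq_matrix",
    "normalize_fot",
    "fot_matrix",
    "fit_rt_model",
    "match_between_runs",
    "filter_and_impute",
    "read_peptides_tsv",
    "read_fasta",
    "write_fasta",
    "write_matrix_tsv",
    "read_matrix_tsv",
]

# observable-peptide bounds: fully tryptic, zero missed cleavages;
# the lower bound mirrors the >=7-aa peptide identification filter
PEPTIDE_MIN_LEN = 7
PEPTIDE_MAX_LEN = 30

FOT_SCALE = 1e5
FOT_FLOOR = 1e-5
DETECTION_FRACTION = 0.30  # strictly more than 30% of samples

_AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")


# ---------------------------------------------------------------------------
# In-silico digestion
# ---------------------------------------------------------------------------


def digest_tryptic(protein_sequence: str) -> list[str]:
    """Fully tryptic fragments: cleave C-terminal to K/R, not before P."""
    seq = protein_sequence
    if not seq:
        raise ValueError("empty protein sequence")
    for i, aa in enumerate(seq):
        if aa not in _AMINO_ACIDS:
            raise ValueError(f"illegal amino acid {aa!r} at position {i}")
    peptides = []
    start = 0
    for i, aa in enumerate(seq):
        if aa in "KR" and (i + 1 == len(seq) or seq[i + 1] != "P"):
            peptides.append(seq[start : i + 1])
            start = i + 1
    if start < len(seq):
        peptides.append(seq[start:])
    return peptides


def count_observable_peptides(protein_sequence: str) -> int:
    """Number of theoretically observable tryptic peptides (length 7-30)."""
    return sum(
        PEPTIDE_MIN_LEN <= len(p) <= PEPTIDE_MAX_LEN
        for p in digest_tryptic(protein_sequence)
    )


# ---------------------------------------------------------------------------
# iBAQ and FOT
# ---------------------------------------------------------------------------


def compute_ibaq(intensities, n_observable: int) -> float:
    """iBAQ = summed peptide intensity / observable-peptide count."""
    intensities = np.asarray(intensities, dtype=float)
    if intensities.size == 0:
        raise ValueError("need at least one evidence row")
    if np.any(intensities < 0):
        raise ValueError("intensities must be >= 0")
    if n_observable < 1:
        raise ValueError("protein has no observable peptide; cannot normalize")
    return float(intensities.sum()) / n_observable


def ibaq_matrix(
    evidence: pd.DataFrame,
    n_observable: dict[str, int],
) -> tuple[pd.DataFrame, list[str]]:
    """Per-run iBAQ values for every protein with evidence.

    Returns (runs x proteins DataFrame with NaN for proteins absent from a
    run, list of proteins excluded because they have no observable
    peptide).
    """
    sums = evidence.groupby(["run_id", "protein"], sort=True)["intensity"].sum()
    mat = sums.unstack("protein")
    excluded = [p for p in mat.columns if n_observable.get(p, 0) < 1]
    if excluded:
        warnings.warn(
            f"{len(excluded)} protein(s) with zero observable peptides excluded",
            stacklevel=2,
        )
        mat = mat.drop(columns=excluded)
    divisor = pd.Series({p: float(n_observable[p]) for p in mat.columns})
    return mat.div(divisor, axis=1), excluded


def normalize_fot(ibaq_by_protein: pd.Series) -> pd.Series:
    """FOT_i = iBAQ_i / sum_j iBAQ_j x 1E5, floored at 1E-5.

    Pre-floor values sum to 1E5; flooring happens after normalization.
    """
    v = ibaq_by_protein.astype(float)
    if (v < 0).any():
        raise ValueError("iBAQ values must be >= 0")
    total = v.sum()
    if total <= 0:
        raise ValueError("all-zero iBAQ vector: no identified proteins")
    fot = v / total * FOT_SCALE
    return fot.clip(lower=FOT_FLOOR)


def fot_matrix(ibaq: pd.DataFrame) -> "AbundanceMatrix":
    """Row-wise FOT normalization of a runs x proteins iBAQ matrix.

    Missing entries (protein not identified in a run) stay missing; the
    FOT denominator is the total iBAQ of identified proteins in that run.
    """
    values = ibaq.copy().astype(float)
    mask = values.isna()
    for run in values.index:
        row = values.loc[run]
        obs = row.dropna()
        values.loc[run, obs.index] = normalize_fot(obs)
    return AbundanceMatrix(values=values, scale="FOT", mask=mask)


# ---------------------------------------------------------------------------
# Abundance matrix container
# ---------------------------------------------------------------------------


@dataclass
class AbundanceMatrix:
    """Samples x features abundance matrix with an explicit missing mask.

    ``scale`` is "FOT" (linear, floored at 1E-5) or "log2FOT".  The mask is
    True where the original value was missing (NaN pre-imputation or
    imputed with the floor).
    """

    values: pd.DataFrame
    scale: str
    mask: pd.DataFrame = None

    def __post_init__(self) -> None:
        if self.scale not in {"FOT", "log2FOT"}:
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.mask is None:
            self.mask = self.values.isna()
        if not self.mask.index.equals(self.values.index) or not self.mask.columns.equals(
            self.values.columns
        ):
            raise ValueError("mask must be aligned with values")

    @property
    def samples(self) -> pd.Index:
        return self.values.index

    @property
    def features(self) -> pd.Index:
        return self.values.columns


def filter_and_impute(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Detection filter, floor imputation and log2 transform.

    Features detected in strictly more than 30% of samples are retained;
    missing entries are imputed with the 1E-5 floor; all values are log2
    transformed.  The missing mask marks imputed cells.
    """
    if matrix.scale != "FOT":
        raise ValueError("expected a FOT-scale matrix")
    if matrix.values.shape[0] < 1:
        raise ValueError("matrix has no samples")
    detected = (~matrix.mask) & matrix.values.notna()
    frac = detected.mean(axis=0)
    keep = frac > DETECTION_FRACTION
    if not keep.any():
        warnings.warn("no feature passes the detection filter", stacklevel=2)
    values = matrix.values.loc[:, keep].copy()
    mask = ~detected.loc[:, keep]
    values = values.where(~mask, FOT_FLOOR)
    values = np.log2(values)
    return AbundanceMatrix(values=values, scale="log2FOT", mask=mask)


# ---------------------------------------------------------------------------
# Retention-time model and match between runs
# ---------------------------------------------------------------------------

MIN_ANCHORS = 6  # quadratic fit keeps >= 3 residual degrees of freedom


@dataclass
class RtModel:
    """Polynomial map from reference RT to target RT (degree 1 or 2)."""

    degree: int
    coefficients: np.ndarray  # highest power first (numpy polyval order)
    r_squared: float
    n_anchors: int

    def predict(self, rt_reference):
        return np.polyval(self.coefficients, rt_reference)


def _poly_fit(x: np.ndarray, y: np.ndarray, degree: int) -> tuple[np.ndarray, float, float]:
    coef = np.polyfit(x, y, degree)
    resid = y - np.polyval(coef, x)
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    n = x.size
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - degree - 1)
    return coef, r2, adj


def fit_rt_model(anchor_pairs) -> RtModel:
    """Fit degree-1 and degree-2 least squares; keep the higher adjusted R².

    Ties go to the linear model.  Requires >= 6 anchor pairs so the
    quadratic keeps at least 3 residual degrees of freedom.
    """
    pairs = np.asarray(anchor_pairs, dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2:
        raise ValueError("anchor pairs must be (rt_reference, rt_target) tuples")
    if pairs.shape[0] < MIN_ANCHORS:
        raise ValueError("insufficient anchors")
    x, y = pairs[:, 0], pairs[:, 1]
    if np.all(x == x[0]):
        raise ValueError("degenerate anchors: all reference RTs identical")
    c1, r2_1, adj1 = _poly_fit(x, y, 1)
    c2, r2_2, adj2 = _poly_fit(x, y, 2)
    if adj2 > adj1:
        return RtModel(degree=2, coefficients=c2, r_squared=max(0.0, min(1.0, r2_2)),
                       n_anchors=pairs.shape[0])
    return RtModel(degree=1, coefficients=c1, r_squared=max(0.0, min(1.0, r2_1)),
                   n_anchors=pairs.shape[0])


def match_between_runs(
    reference: pd.DataFrame,
    target: pd.DataFrame,
    target_xics: pd.DataFrame,
    rt_tolerance: float = 1.0,
) -> pd.DataFrame:
    """Transfer identifications from a reference run into a target run.

    ``reference`` and ``target`` are evidence tables (columns run_id,
    peptide, protein, intensity, rt, observed); ``target_xics`` lists
    candidate XICs detected in the target run (columns peptide, rt,
    intensity).  For each peptide identified in the reference but absent
    from the target, the target RT is predicted from a regression on
    shared peptides; if a candidate XIC for the peptide lies within
    ``rt_tolerance`` of the prediction, a transferred record flagged
    ``observed=False`` is appended.  Returns the augmented target table.
    """
    shared = pd.merge(
        reference[["peptide", "rt"]],
        target[["peptide", "rt"]],
        on="peptide",
        suffixes=("_ref", "_tgt"),
    )
    model = fit_rt_model(shared[["rt_ref", "rt_tgt"]].to_numpy())
    target_peptides = set(target["peptide"])
    missing = reference[~reference["peptide"].isin(target_peptides)]
    run_id = target["run_id"].iloc[0] if len(target) else None
    new_rows = []
    for _, row in missing.iterrows():
        predicted = float(model.predict(row["rt"]))
        cands = target_xics[target_xics["peptide"] == row["peptide"]]
        if cands.empty:
            continue
        dt = (cands["rt"] - predicted).abs()
        best = dt.idxmin()
        if dt.loc[best] <= rt_tolerance:
            new_rows.append(
                {
                    "run_id": run_id,
                    "peptide": row["peptide"],
                    "protein": row["protein"],
                    "intensity": float(cands.loc[best, "intensity"]),
                    "rt": float(cands.loc[best, "rt"]),
                    "observed": False,
                }
            )
    if not new_rows:
        return target.copy()
    return pd.concat([target, pd.DataFrame(new_rows)], ignore_index=True)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

EVIDENCE_COLUMNS = ["run_id", "peptide", "protein", "intensity", "rt", "observed"]


def read_peptides_tsv(path) -> pd.DataFrame:
    ev = pd.read_csv(path, sep="\t")
    required = {"run_id", "peptide", "protein", "intensity", "rt"}
    missing = required - set(ev.columns)
    if missing:
        raise ValueError(f"peptide table missing columns: {sorted(missing)}")
    if "observed" not in ev.columns:
        ev["observed"] = True
    if (ev["intensity"] < 0).any() or (ev["rt"] < 0).any():
        raise ValueError("intensity and rt must be >= 0")
    return ev[EVIDENCE_COLUMNS]


def read_fasta(path) -> dict[str, str]:
    """Read protein sequences, id -> sequence."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    seqio_write(records, str(path), "fasta")


def write_matrix_tsv(matrix: AbundanceMatrix, path, mask_path=None) -> None:
    """Write the matrix with a '#scale=' header line; mask optional."""
    with open(path, "w") as fh:
        fh.write(f"#scale={matrix.scale}\n")
        matrix.values.to_csv(fh, sep="\t", index_label="sample")
    if mask_path is not None:
        matrix.mask.astype(int).to_csv(mask_path, sep="\t", index_label="sample")


def read_matrix_tsv(path, mask_path=None) -> AbundanceMatrix:
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("#scale="):
            raise ValueError("matrix file must start with a '#scale=' line")
        scale = header.split("=", 1)[1]
        values = pd.read_csv(fh, sep="\t", index_col="sample")
    mask = None
    if mask_path is not None:
        mask = pd.read_csv(mask_path, sep="\t", index_col="sample").astype(bool)
    return AbundanceMatrix(values=values, scale=scale, mask=mask)
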