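"""Single-sample gene-set enrichment and derived scores.

The scorer is a weighted Kolmogorov-Smirnov running sum over a sample's
rank-ordered profile: set members increment by |r|^w normalized over the
set's total weight, non-members decrement by 1/(N - n_set), and the
enrichment score (ES) is the signed area under the running sum.  NES
normalizes by the mean |ES| of size-matched random sets.  Defaults follow
the PTM-SEA parameterization: weight 0.75, rank sample normalization,
area-under-RES statistic, 1000 permutations, minimum overlap 5, NES
output.

Derived scores built on the same machinery: the DDR score (mean of
across-sample-standardized phospho abundances of DNA-damage-response
markers) and regulon/TF activity (ssGSEA over transcriptional target
sets, minimum set size 10).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .quant import AbundanceMatrix

__all__ = [
    "GeneSetCollection",
    "EnrichmentParams",
    "GeneSetSkipped",
    "DdrScore",
    "ssgsea_es",
    "ssgsea_nes",
    "score_matrix",
    "ddr_score",
    "regulon_activity",
    "read_gmt",
    "write_gmt",
]

REGULON_MIN_SIZE = 10


class GeneSetSkipped(Exception):
    """Raised when a set cannot be scored; carries the reason."""

    def __init__(self, reason: str):
        self.reason = reason
        super().__init__(reason)


@dataclass
class GeneSetCollection:
    """Named gene sets, optionally with member signs (+1/-1)."""

    sets: dict[str, list[str]]
    signs: dict[str, dict[str, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if len(set(members)) != len(members):
                raise ValueError(f"duplicate members in gene set {name!r}")

    def __iter__(self):
        return iter(self.sets.items())

    def __len__(self) -> int:
        return len(self.sets)


@dataclass
class EnrichmentParams:
    """Scoring parameters; defaults are the printed PTM-SEA block."""

    weight: float = 0.75
    sample_norm: str = "rank"
    n_permutations: int = 1000
    min_overlap: int = 5
    output: str = "NES"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.weight < 0:
            raise ValueError("weight must be >= 0")
        if self.sample_norm not in {"rank", "none"}:
            raise ValueError("sample_norm must be 'rank' or 'none'")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.min_overlap < 1:
            raise ValueError("min_overlap must be >= 1")
        if self.output not in {"ES", "NES"}:
            raise ValueError("output must be 'ES' or 'NES'")


# ---------------------------------------------------------------------------
# Core running-sum scorer
# ---------------------------------------------------------------------------


def _prepare_profile(profile: pd.Series, params: EnrichmentParams):
    """Rank-normalize (if requested) and order the profile descending.

    Ties are broken by a seeded random shuffle of feature order followed
    by a stable sort, so the outcome is deterministic for a given seed but
    not biased toward input ordering.
    """
    values = profile.to_numpy(dtype=float)
    n = values.size
    rng = np.random.default_rng(params.seed)
    shuffle = rng.permutation(n)
    # stable sort descending on shuffled order
    order = shuffle[np.argsort(-values[shuffle], kind="mergesort")]
    if params.sample_norm == "rank":
        # highest value gets rank N, lowest rank 1
        r_sorted = np.arange(n, 0, -1, dtype=float)
    else:
        r_sorted = values[order]
    features_sorted = profile.index.to_numpy()[order]
    return features_sorted, r_sorted


def _es_from_sorted(
    features_sorted: np.ndarray,
    r_sorted: np.ndarray,
    member_mask: np.ndarray,
    weight: float,
) -> float:
    n = r_sorted.size
    n_set = int(member_mask.sum())
    if n_set == 0 or n_set == n:
        raise GeneSetSkipped("degenerate set size")
    w = np.abs(r_sorted) ** weight
    hit_w = np.where(member_mask, w, 0.0)
    total = hit_w.sum()
    if total == 0:
        raise GeneSetSkipped("zero total hit weight")
    p_hit = np.cumsum(hit_w) / total
    p_miss = np.cumsum(~member_mask) / (n - n_set)
    res = p_hit - p_miss
    return float(res.sum() / n)  # signed area under the running sum


def ssgsea_es(profile: pd.Series, gene_set, params: EnrichmentParams | None = None) -> float:
    """Single-sample enrichment score of one gene set in one profile.

    Raises :class:`GeneSetSkipped` (reason ``"min.overlap"``) when fewer
    than ``params.min_overlap`` set members are present in the profile.
    """
    params = params or EnrichmentParams()
    members = set(gene_set)
    overlap = members & set(profile.index)
    if len(overlap) < params.min_overlap:
        raise GeneSetSkipped("min.overlap")
    features_sorted, r_sorted = _prepare_profile(profile, params)
    mask = np.isin(features_sorted, list(members))
    return _es_from_sorted(features_sorted, r_sorted, mask, params.weight)


def ssgsea_nes(profile: pd.Series, gene_set, params: EnrichmentParams | None = None) -> float:
    """Permutation-normalized enrichment score.

    NES = ES / mean |ES| over ``n_permutations`` random sets of the same
    size drawn without replacement from the profile's features; the sign
    of ES is preserved.
    """
    params = params or EnrichmentParams()
    members = set(gene_set)
    overlap = members & set(profile.index)
    if len(overlap) < params.min_overlap:
        raise GeneSetSkipped("min.overlap")
    features_sorted, r_sorted = _prepare_profile(profile, params)
    mask = np.isin(features_sorted, list(members))
    es = _es_from_sorted(features_sorted, r_sorted, mask, params.weight)

    n = r_sorted.size
    n_set = int(mask.sum())
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 0x9E3779B9]))
    # vectorized permutation null: P x N membership indicators built from
    # uniform random subsets of size n_set
    w = np.abs(r_sorted) ** params.weight
    p_count = params.n_permutations
    idx = np.argsort(rng.random((p_count, n)), axis=1)[:, :n_set]
    member = np.zeros((p_count, n), dtype=bool)
    np.put_along_axis(member, idx, True, axis=1)
    hit_w = np.where(member, w, 0.0)
    p_hit = np.cumsum(hit_w, axis=1) / hit_w.sum(axis=1, keepdims=True)
    p_miss = np.cumsum(~member, axis=1) / (n - n_set)
    perm_es = (p_hit - p_miss).sum(axis=1) / n
    denom = float(np.abs(perm_es).mean())
    if denom == 0:
        raise ValueError("degenerate profile: permutation mean |ES| is zero")
    return es / denom


def _score_one(profile: pd.Series, members, signs, params: EnrichmentParams) -> float:
    scorer = ssgsea_nes if params.output == "NES" else ssgsea_es
    if signs:
        up = [m for m in members if signs.get(m, 1) >= 0]
        down = [m for m in members if signs.get(m, 1) < 0]
        score = 0.0
        if up:
            score += scorer(profile, up, params)
        if down:
            score -= scorer(profile, down, params)
        return score
    return scorer(profile, members, params)


def score_matrix(
    matrix: AbundanceMatrix,
    sets: GeneSetCollection,
    params: EnrichmentParams | None = None,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Score every (sample, set) pair; returns (samples x sets, skipped).

    Sets that cannot be scored in any sample are reported in ``skipped``
    with the reason.
    """
    params = params or EnrichmentParams()
    if matrix.scale != "log2FOT":
        raise ValueError("expected a log2-scale matrix")
    scores: dict[str, list[float]] = {}
    skipped: dict[str, str] = {}
    for name, members in sets:
        signs = sets.signs.get(name)
        col = []
        try:
            for sample in matrix.samples:
                col.append(_score_one(matrix.values.loc[sample], members, signs, params))
        except GeneSetSkipped as exc:
            skipped[name] = exc.reason
            continue
        scores[name] = col
    return pd.DataFrame(scores, index=matrix.samples), skipped


# ---------------------------------------------------------------------------
# DDR score
# ---------------------------------------------------------------------------


@dataclass
class DdrScore:
    """Per-sample DNA-damage-response score and the markers used."""

    scores: pd.Series
    markers_used: list[str]


def ddr_score(phospho_matrix: AbundanceMatrix, markers) -> DdrScore:
    """Mean of per-marker standardized phospho abundances.

    Each marker's values are standardized to mean 0 / SD 1 (sample SD,
    n-1) across samples; a sample's score is the mean over markers with
    data.  Zero-variance markers are dropped with a warning.
    """
    if phospho_matrix.values.shape[0] < 2:
        raise ValueError("need >= 2 samples")
    present = [m for m in markers if m in phospho_matrix.features]
    if not present:
        raise ValueError("no DDR marker present in the matrix")
    sub = phospho_matrix.values[present].astype(float)
    sd = sub.std(axis=0, ddof=1)
    degenerate = sd[sd == 0].index.tolist()
    if degenerate:
        warnings.warn(f"zero-variance markers dropped: {degenerate}", stacklevel=2)
        sub = sub.drop(columns=degenerate)
        sd = sd.drop(index=degenerate)
    if sub.shape[1] == 0:
        raise ValueError("all markers have zero variance")
    z = (sub - sub.mean(axis=0)) / sd
    return DdrScore(scores=z.mean(axis=1), markers_used=list(sub.columns))


# ---------------------------------------------------------------------------
# Regulon / TF activity
# ---------------------------------------------------------------------------


def regulon_activity(
    matrix: AbundanceMatrix,
    regulons: GeneSetCollection,
    min_size: int = REGULON_MIN_SIZE,
    params: EnrichmentParams | None = None,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """ssGSEA activity over target-gene sets; regulons below min_size skipped."""
    params = params or EnrichmentParams()
    kept = {}
    skipped = {}
    for name, members in regulons:
        if len(members) < min_size:
            skipped[name] = "min_size"
        else:
            kept[name] = members
    scores, more_skipped = score_matrix(
        matrix, GeneSetCollection(kept, regulons.signs), params
    )
    skipped.update(more_skipped)
    return scores, skipped


# ---------------------------------------------------------------------------
# GMT I/O
# ---------------------------------------------------------------------------


def read_gmt(path) -> GeneSetCollection:
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            name, _description, *members = parts
            sets[name] = [m for m in members if m]
    return GeneSetCollection(sets)


def write_gmt(sets: GeneSetCollection, path, descriptions: dict[str, str] | None = None) -> None:
    descriptions = descriptions or {}
    with open(path, "w") as fh:
        for name, members in sets:
            desc = descriptions.get(name, "na")
            fh.write("\t".join([name, desc, *members]) + "\n")
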