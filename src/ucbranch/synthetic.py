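"""Seeded synthetic multi-omics cohort generator.

Emulates the latent structure the downstream analysis assumes, on a
cohort spanning normal tissue, precancerous lesions (hyperplasia, UPUMP),
benign papilloma, papillary tumors (LGPC/HGPC), flat carcinoma in situ
(CIS) and invasive cancer:

* protein abundances log2-normal per protein with branch-discriminating
  panel effects (papillary vs CIS latent branch) and abundance-dependent
  logistic missingness (left-censoring-like, as in FFPE label-free data);
* peptide-level evidence with retention times, so the quantification
  chain (iBAQ -> FOT -> filtering/imputation) runs on realistic input;
* phosphoprotein abundances with DNA-damage-response markers elevated in
  CIS and invasive samples;
* mutation records drawn from class-dependent mixtures of reference SBS
  signatures, with explicit flanking bases (no genome needed) and an
  HRAS-hotspot indicator for papilloma (83% carriers, 8/10 Q61R);
* copy-number segments with an 8p12 deletion (log2 -1.2) enriched in the
  metastatic invasive subgroup, plus a designated cis-effect protein;
* proportional-hazards survival with a worse hazard for the CIS-derived
  branch and independent exponential censoring.

Every quantity the downstream recovery tests check is recorded in a
TruthRecord.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import cna as _cna
from . import mutsig as _mutsig
from . import quant as _quant
from .enrich import GeneSetCollection, write_gmt
from .quant import AbundanceMatrix

__all__ = [
    "CLASSES",
    "CLASS_BRANCH",
    "CohortConfig",
    "TruthRecord",
    "CohortBundle",
    "generate_cohort",
    "generate_mutation_table",
    "synthetic_signature_set",
    "default_arms",
]

CLASSES = (
    "Normal",
    "Hyperplasia",
    "UPUMP",
    "Papilloma",
    "LGPC",
    "HGPC",
    "CIS",
    "Invasive",
)

#: latent origin branch per histology class; invasive samples draw theirs
CLASS_BRANCH = {
    "Normal": "none",
    "Hyperplasia": "none",
    "UPUMP": "none",
    "Papilloma": "papillary",
    "LGPC": "papillary",
    "HGPC": "papillary",
    "CIS": "cis",
}

_HIGH_GRADE = {"HGPC", "CIS", "Invasive"}

SIGNATURE_IDS = ("SIG_A", "SIG_B", "SIG_C", "SIG_D")

#: class-dependent mixtures over the synthetic reference signatures
DEFAULT_EXPOSURE_PROFILES = {
    "Normal": {"SIG_A": 0.8, "SIG_B": 0.2},
    "Hyperplasia": {"SIG_A": 0.8, "SIG_B": 0.2},
    "UPUMP": {"SIG_A": 0.7, "SIG_B": 0.3},
    "Papilloma": {"SIG_A": 0.5, "SIG_C": 0.5},
    "LGPC": {"SIG_A": 0.4, "SIG_B": 0.2, "SIG_C": 0.4},
    "HGPC": {"SIG_A": 0.4, "SIG_B": 0.2, "SIG_C": 0.4},
    "CIS": {"SIG_A": 0.3, "SIG_B": 0.1, "SIG_D": 0.6},
    "Invasive": {"SIG_A": 0.3, "SIG_B": 0.1, "SIG_D": 0.6},
}


def synthetic_signature_set(ids=SIGNATURE_IDS) -> pd.DataFrame:
    """Well-separated synthetic reference signatures (96 x k).

    Signature j puts 92% of its mass uniformly on its own block of 96/k
    contexts and spreads the rest uniformly; deterministic by design
    (part of the stated world, not a random draw).
    """
    k = len(ids)
    block = 96 // k
    mat = np.full((96, k), 0.08 / 96)
    for j in range(k):
        mat[j * block : (j + 1) * block, j] += 0.92 / block
    sig = pd.DataFrame(mat, index=list(_mutsig.CONTEXTS_96), columns=list(ids))
    return _mutsig.validate_signature_set(sig / sig.sum(axis=0))


def default_arms() -> pd.DataFrame:
    """Toy arm definitions (0-based half-open) including an 8p arm."""
    return pd.DataFrame(
        [
            ("1p", "chr1", 0, 120_000_000),
            ("1q", "chr1", 120_000_000, 240_000_000),
            ("8p", "chr8", 0, 45_000_000),
            ("8q", "chr8", 45_000_000, 145_000_000),
        ],
        columns=["arm", "chrom", "start", "end"],
    )


#: interval of the simulated 8p12 deletion within the 8p arm
DEL_8P12 = ("chr8", 30_000_000, 40_000_000)
DEL_8P12_LOG2 = -1.2  # exceeds the |log2| = 1 call threshold


@dataclass
class CohortConfig:
    """Generator parameters; defaults are the stated world of the study.

    ``n_per_class`` is an int (same count for every class) or a mapping
    class -> count (0 removes a class).
    """

    n_per_class: int | dict = 12
    classes: tuple = CLASSES
    n_proteins: int = 600
    panel_size: int = 18
    effect_log2: float = 1.5
    noise_sd: float = 1.0
    dropout_midpoint: float = 4.0
    dropout_slope: float = 0.8
    hras_papilloma_prob: float = 0.83
    q61r_frac: float = 0.8
    mutation_rate: float = 100.0
    exposure_profiles: dict = field(default_factory=lambda: {
        c: dict(p) for c, p in DEFAULT_EXPOSURE_PROFILES.items()
    })
    cis_derived_hr: float = 2.0
    censor_rate: float = 0.01
    baseline_hazard: float = 0.0139  # ln 2 / 50 months
    invasive_cis_frac: float = 0.38
    met_prob_cis: float = 0.5
    met_prob_puc: float = 0.15
    met_prob_other: float = 0.02
    del8p12_prob_met: float = 0.8
    del8p12_prob_other: float = 0.05
    n_phospho: int = 200
    n_ddr_markers: int = 20
    seed: int = 0

    def class_counts(self) -> dict[str, int]:
        if isinstance(self.n_per_class, dict):
            counts = {c: int(self.n_per_class.get(c, 0)) for c in self.classes}
        else:
            counts = {c: int(self.n_per_class) for c in self.classes}
        return {c: n for c, n in counts.items() if n > 0}

    def validate(self) -> None:
        if self.effect_log2 < 0:
            raise ValueError("effect_log2 must be >= 0")
        if not 0 <= self.hras_papilloma_prob <= 1:
            raise ValueError("hras_papilloma_prob must be in [0, 1]")
        if not 0 <= self.q61r_frac <= 1:
            raise ValueError("q61r_frac must be in [0, 1]")
        if self.mutation_rate < 0:
            raise ValueError("mutation_rate must be >= 0")
        if self.n_proteins < self.panel_size + 16:
            raise ValueError(
                "n_proteins must exceed panel_size + 16 (panel, cis-effect "
                "gene, repressor and regulon targets must be distinct)"
            )
        if self.cis_derived_hr <= 0:
            raise ValueError("cis_derived_hr must be > 0")
        counts = self.class_counts()
        if not counts:
            raise ValueError("no classes with samples")
        for c, n in counts.items():
            if n < 2:
                raise ValueError(
                    f"class {c!r} has {n} sample(s); two-group comparisons need >= 2"
                )
        sig_ids = set(SIGNATURE_IDS)
        for c in counts:
            profile = self.exposure_profiles.get(c)
            if profile is None:
                raise ValueError(f"no exposure profile for class {c!r}")
            w = np.array(list(profile.values()), dtype=float)
            if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
                raise ValueError(f"exposure profile of {c!r} must be a distribution")
            unknown = set(profile) - sig_ids
            if unknown:
                raise ValueError(f"exposure profile of {c!r} references unknown "
                                 f"signatures {sorted(unknown)}")


@dataclass
class TruthRecord:
    """Ground truth for recovery tests."""

    panel_up_papillary: list[str]
    panel_up_cis: list[str]
    ddr_marker_ids: list[str]
    exposures: dict[str, dict[str, float]]
    del8p12: dict[str, bool]
    true_hr: float
    cis_effect_gene: str
    hras_carriers: list[str]
    regulon_name: str
    repressor_id: str
    injected_pathway: str

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)


@dataclass
class CohortBundle:
    cohort: pd.DataFrame
    truth: TruthRecord
    peptides: pd.DataFrame
    sequences: dict[str, str]
    protein_truth: pd.DataFrame  # samples x proteins, true log2 abundance
    phospho: AbundanceMatrix
    mutations: pd.DataFrame
    segments: pd.DataFrame
    arms: pd.DataFrame
    signatures: pd.DataFrame
    gene_sets: GeneSetCollection
    config: CohortConfig

    def write(self, outdir) -> None:
        """Write the bundle as plain-text files (TSV/GMT/JSON/FASTA)."""
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.cohort.to_csv(out / "clinical.tsv", sep="\t")
        self.peptides.to_csv(out / "peptides.tsv", sep="\t", index=False)
        _quant.write_fasta(self.sequences, out / "proteins.fasta")
        _quant.write_matrix_tsv(self.phospho, out / "phospho.tsv",
                                mask_path=out / "phospho.mask.tsv")
        self.mutations.to_csv(out / "mutations.maf.tsv", sep="\t", index=False)
        _cna.write_seg_tsv(self.segments, out / "segments.seg.tsv")
        self.arms.to_csv(out / "arms.tsv", sep="\t", index=False)
        _mutsig.write_signatures_tsv(self.signatures, out / "signatures.tsv")
        write_gmt(self.gene_sets, out / "gene_sets.gmt")
        self.truth.to_json(out / "truth.json")


# ---------------------------------------------------------------------------
# Sub-generators
# ---------------------------------------------------------------------------


def _make_cohort_table(config: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for cls, n in config.class_counts().items():
        for i in range(n):
            sample = f"{cls[:3].upper()}_{i:03d}"
            if cls == "Invasive":
                branch = "cis" if rng.random() < config.invasive_cis_frac else "papillary"
                derived = "CIS-derived" if branch == "cis" else "PUC-derived"
            else:
                branch = CLASS_BRANCH[cls]
                derived = ""
            grade = "high" if cls in _HIGH_GRADE else "low"
            rows.append(
                {
                    "sample": sample,
                    "histology_class": cls,
                    "grade": grade,
                    "latent_branch": branch,
                    "derived_label": derived,
                    "metastasis": 0,
                    "survival_time": np.nan,
                    "event": 0,
                }
            )
    cohort = pd.DataFrame(rows).set_index("sample")
    # metastasis coupled to the latent branch of invasive samples
    for sample, row in cohort.iterrows():
        if row["histology_class"] == "Invasive":
            p = config.met_prob_cis if row["latent_branch"] == "cis" else config.met_prob_puc
        else:
            p = config.met_prob_other
        cohort.loc[sample, "metastasis"] = int(rng.random() < p)
    # exponential PH survival, worse hazard for the CIS branch
    hazard = np.where(
        cohort["latent_branch"] == "cis",
        config.baseline_hazard * config.cis_derived_hr,
        config.baseline_hazard,
    )
    t_event = rng.exponential(1.0 / hazard)
    t_censor = rng.exponential(1.0 / config.censor_rate, size=len(cohort))
    cohort["survival_time"] = np.maximum(np.minimum(t_event, t_censor), 1e-3)
    cohort["event"] = (t_event <= t_censor).astype(int)
    cohort["metastasis"] = cohort["metastasis"].astype(int)
    return cohort


def _random_tryptic_peptide(rng: np.random.Generator) -> str:
    interior = "ACDEFGHILMNQSTVWY"  # no K/R (missed cleavage) and no P
    length = int(rng.integers(7, 21))
    body = "".join(rng.choice(list(interior), size=length - 1))
    return body + ("K" if rng.random() < 0.5 else "R")


def _make_proteome(config, cohort, rng):
    """True log2 abundances, sequences, and effect assignments."""
    n_prot = config.n_proteins
    proteins = [f"P{i:04d}" for i in range(n_prot)]
    base = rng.uniform(2.0, 12.0, size=n_prot)

    half = config.panel_size // 2
    panel_up_pap = proteins[:half]
    panel_up_cis = proteins[half : config.panel_size]
    idx_after_panel = config.panel_size
    cis_effect_gene = proteins[idx_after_panel]
    repressor = proteins[idx_after_panel + 1]
    regulon_targets = proteins[idx_after_panel + 2 : idx_after_panel + 14]
    pathway_members = proteins[idx_after_panel + 14 : idx_after_panel + 34]

    branch = cohort["latent_branch"].to_numpy()
    n_samples = len(cohort)
    truth = np.tile(base, (n_samples, 1))

    shift = config.effect_log2 / 2.0
    pap_mask = branch == "papillary"
    cis_mask = branch == "cis"
    for pid in panel_up_pap:
        j = proteins.index(pid)
        truth[pap_mask, j] += shift
        truth[cis_mask, j] -= shift
    for pid in panel_up_cis:
        j = proteins.index(pid)
        truth[cis_mask, j] += shift
        truth[pap_mask, j] -= shift

    # injected pathway: up in the CIS branch (power check for scoring)
    for pid in pathway_members:
        truth[cis_mask, proteins.index(pid)] += 1.0

    # AP-1-style regulon: targets co-vary negatively with a repressor
    latent = rng.normal(0.0, 1.0, size=n_samples)
    truth[:, proteins.index(repressor)] += latent
    for pid in regulon_targets:
        truth[:, proteins.index(pid)] -= 0.6 * latent

    truth += rng.normal(0.0, config.noise_sd, size=truth.shape)

    sequences = {}
    n_obs = {}
    for pid in proteins:
        k = int(rng.integers(2, 5))
        sequences[pid] = "".join(_random_tryptic_peptide(rng) for _ in range(k))
        n_obs[pid] = k
    protein_truth = pd.DataFrame(truth, index=cohort.index, columns=proteins)
    assignments = {
        "panel_up_papillary": panel_up_pap,
        "panel_up_cis": panel_up_cis,
        "cis_effect_gene": cis_effect_gene,
        "repressor": repressor,
        "regulon_targets": regulon_targets,
        "pathway_members": pathway_members,
    }
    return protein_truth, sequences, n_obs, assignments


def _dropout_mask(truth_log2: np.ndarray, config, rng) -> np.ndarray:
    """True = missing; probability decreases logistically with abundance."""
    p_miss = 1.0 / (1.0 + np.exp(config.dropout_slope * (truth_log2 - config.dropout_midpoint)))
    return rng.random(truth_log2.shape) < p_miss


def _make_peptides(protein_truth, sequences, n_obs, config, rng) -> pd.DataFrame:
    """Peptide evidence whose per-protein iBAQ is proportional to truth."""
    proteins = list(protein_truth.columns)
    peptide_seqs = {}
    peptide_rt = {}
    peptide_frac = {}
    for pid in proteins:
        peps = _quant.digest_tryptic(sequences[pid])
        peps = [p for p in peps if 7 <= len(p) <= 30]
        fracs = rng.dirichlet(np.full(len(peps), 5.0))
        peptide_seqs[pid] = peps
        peptide_frac[pid] = fracs
        peptide_rt[pid] = rng.uniform(5.0, 120.0, size=len(peps))

    linear = np.power(2.0, protein_truth.to_numpy())
    missing = _dropout_mask(protein_truth.to_numpy(), config, rng)
    run_scale = np.exp(rng.normal(0.0, 0.3, size=len(protein_truth)))
    rt_offset = rng.normal(0.0, 2.0, size=len(protein_truth))
    rt_slope = rng.normal(1.0, 0.02, size=len(protein_truth))

    cols = {"run_id": [], "peptide": [], "protein": [], "intensity": [], "rt": []}
    for si, sample in enumerate(protein_truth.index):
        present = np.flatnonzero(~missing[si])
        for j in present:
            pid = proteins[j]
            total = linear[si, j] * n_obs[pid] * run_scale[si]
            for pep, frac, rt in zip(peptide_seqs[pid], peptide_frac[pid], peptide_rt[pid]):
                cols["run_id"].append(sample)
                cols["peptide"].append(pep)
                cols["protein"].append(pid)
                cols["intensity"].append(total * frac)
                cols["rt"].append(max(0.0, rt_offset[si] + rt_slope[si] * rt))
    ev = pd.DataFrame(cols)
    ev["observed"] = True
    return ev


def _make_phospho(config, cohort, rng):
    n_ddr = config.n_ddr_markers
    ddr_ids = [f"DDR{i:02d}_pS" for i in range(n_ddr)]
    other_ids = [f"PH{i:04d}" for i in range(config.n_phospho - n_ddr)]
    features = ddr_ids + other_ids
    base = rng.uniform(2.0, 10.0, size=len(features))
    truth = np.tile(base, (len(cohort), 1))
    elevated = cohort["histology_class"].isin(["CIS", "Invasive"]).to_numpy()
    truth[np.ix_(elevated, np.arange(n_ddr))] += 1.2
    truth += rng.normal(0.0, config.noise_sd, size=truth.shape)
    missing = _dropout_mask(truth, config, rng)
    linear = np.power(2.0, truth)
    values = np.where(missing, np.nan, linear)
    # per-sample FOT renormalization over observed sites
    row_sums = np.nansum(values, axis=1, keepdims=True)
    values = values / row_sums * _quant.FOT_SCALE
    values = np.where(np.isnan(values), np.nan, np.maximum(values, _quant.FOT_FLOOR))
    mat = AbundanceMatrix(
        values=pd.DataFrame(values, index=cohort.index, columns=features),
        scale="FOT",
    )
    return mat, ddr_ids


def generate_mutation_table(
    cohort: pd.DataFrame,
    signatures: pd.DataFrame,
    config: CohortConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Draw per-sample mutation records from class exposure mixtures.

    Each sample's mutation count is Poisson(mutation_rate); contexts are
    i.i.d. draws from the class's exposure-weighted signature mixture.
    Records carry ref/alt and explicit flanking bases; half are emitted on
    the purine strand (reverse-complemented) to exercise catalog folding.
    Papilloma samples carry an HRAS hotspot record with the configured
    probability (Q61R for the configured fraction, otherwise G12V).
    """
    rng = rng or np.random.default_rng(config.seed)
    signatures = _mutsig.validate_signature_set(signatures)
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    contexts = list(_mutsig.CONTEXTS_96)
    rows = []
    pos_counter = 1000
    hras_carriers = []
    for sample, row in cohort.iterrows():
        profile = config.exposure_profiles[row["histology_class"]]
        unknown = set(profile) - set(signatures.columns)
        if unknown:
            raise ValueError(f"exposure profile references unknown signatures {sorted(unknown)}")
        mix = np.zeros(96)
        for sid, w in profile.items():
            mix += w * signatures[sid].to_numpy()
        m = int(rng.poisson(config.mutation_rate))
        if m > 0:
            counts = rng.multinomial(m, mix)
            for ci in np.flatnonzero(counts):
                cat = contexts[ci]
                f5, ref, alt, f3 = cat[0], cat[2], cat[4], cat[6]
                for _ in range(int(counts[ci])):
                    pos_counter += 17
                    if rng.random() < 0.5:  # emit on the purine strand
                        r, a = comp[ref], comp[alt]
                        ff5, ff3 = comp[f3], comp[f5]
                    else:
                        r, a, ff5, ff3 = ref, alt, f5, f3
                    rows.append(
                        {
                            "sample": sample,
                            "chrom": "chr1",
                            "pos": pos_counter,
                            "ref": r,
                            "alt": a,
                            "flank5": ff5,
                            "flank3": ff3,
                            "gene": f"G{int(rng.integers(0, 500)):04d}",
                            "protein_change": "",
                        }
                    )
        if row["histology_class"] == "Papilloma" and rng.random() < config.hras_papilloma_prob:
            hras_carriers.append(sample)
            q61r = rng.random() < config.q61r_frac
            pos_counter += 17
            rows.append(
                {
                    "sample": sample,
                    "chrom": "chr11",
                    "pos": pos_counter,
                    # Q61R: CAA->CGA on the coding strand (A>G, T[A>G]A context
                    # before strand folding); G12V: GGT->GTT (G>T)
                    "ref": "A" if q61r else "G",
                    "alt": "G" if q61r else "T",
                    "flank5": "T" if q61r else "G",
                    "flank3": "A" if q61r else "T",
                    "gene": "HRAS",
                    "protein_change": "Q61R" if q61r else "G12V",
                }
            )
    columns = ["sample", "chrom", "pos", "ref", "alt", "flank5", "flank3", "gene",
               "protein_change"]
    table = pd.DataFrame(rows, columns=columns)
    table.attrs["hras_carriers"] = hras_carriers
    return table


def _make_segments(config, cohort, rng):
    arms = default_arms()
    del_chrom, del_start, del_end = DEL_8P12
    rows = []
    carriers = {}
    for sample, row in cohort.iterrows():
        if row["histology_class"] == "Invasive" and row["metastasis"] == 1:
            p_del = config.del8p12_prob_met
        else:
            p_del = config.del8p12_prob_other
        carrier = bool(rng.random() < p_del)
        carriers[sample] = carrier
        for arm in arms.itertuples(index=False):
            if arm.arm == "8p":
                # split the arm around the 8p12 interval
                pieces = [(arm.start, del_start), (del_start, del_end), (del_end, arm.end)]
                for start, end in pieces:
                    log2 = rng.normal(0.0, 0.08)
                    if carrier and start == del_start:
                        log2 = DEL_8P12_LOG2 + rng.normal(0.0, 0.05)
                    rows.append((sample, arm.chrom, start, end, log2))
            else:
                n_seg = int(rng.integers(2, 5))
                cuts = np.sort(rng.integers(arm.start + 1, arm.end, size=n_seg - 1))
                bounds = [arm.start, *cuts.tolist(), arm.end]
                for start, end in zip(bounds[:-1], bounds[1:]):
                    if end > start:
                        rows.append((sample, arm.chrom, start, end, rng.normal(0.0, 0.08)))
    segments = pd.DataFrame(rows, columns=_cna.SEG_COLUMNS)
    return segments, arms, carriers


# ---------------------------------------------------------------------------
# Top-level generator
# ---------------------------------------------------------------------------


def generate_cohort(config: CohortConfig) -> CohortBundle:
    """Generate a full, internally consistent synthetic cohort bundle.

    Deterministic given ``config.seed``: identical configs yield
    bit-identical bundles.
    """
    config.validate()
    streams = np.random.SeedSequence(config.seed).spawn(6)
    rngs = [np.random.default_rng(s) for s in streams]

    cohort = _make_cohort_table(config, rngs[0])
    protein_truth, sequences, n_obs, assign = _make_proteome(config, cohort, rngs[1])
    peptides = _make_peptides(protein_truth, sequences, n_obs, config, rngs[2])
    phospho, ddr_ids = _make_phospho(config, cohort, rngs[3])
    signatures = synthetic_signature_set()
    mutations = generate_mutation_table(cohort, signatures, config, rngs[4])
    segments, arms, del_carriers = _make_segments(config, cohort, rngs[5])

    # cis-effect: carriers of the 8p12 deletion lose the designated protein
    gene = assign["cis_effect_gene"]
    carrier_mask = cohort.index.map(del_carriers).to_numpy(dtype=bool)
    protein_truth.loc[carrier_mask, gene] += DEL_8P12_LOG2
    # regenerate that protein's evidence consistently: simplest is to scale
    # its peptide intensities in carrier runs
    sel = peptides["protein"] == gene
    in_carrier = peptides["run_id"].isin(cohort.index[carrier_mask])
    peptides.loc[sel & in_carrier, "intensity"] *= 2.0**DEL_8P12_LOG2

    exposures = {
        str(s): dict(config.exposure_profiles[cohort.loc[s, "histology_class"]])
        for s in cohort.index
    }
    gene_sets = GeneSetCollection(
        {
            "INJECTED_PATHWAY": list(assign["pathway_members"]),
            "AP1_REGULON": list(assign["regulon_targets"]),
            "DECOY_SET_1": list(protein_truth.columns[-20:]),
            "DECOY_SET_2": list(protein_truth.columns[-40:-20]),
        }
    )
    truth = TruthRecord(
        panel_up_papillary=list(assign["panel_up_papillary"]),
        panel_up_cis=list(assign["panel_up_cis"]),
        ddr_marker_ids=list(ddr_ids),
        exposures=exposures,
        del8p12={str(k): bool(v) for k, v in del_carriers.items()},
        true_hr=config.cis_derived_hr,
        cis_effect_gene=gene,
        hras_carriers=list(mutations.attrs.get("hras_carriers", [])),
        regulon_name="AP1_REGULON",
        repressor_id=assign["repressor"],
        injected_pathway="INJECTED_PATHWAY",
    )
    return CohortBundle(
        cohort=cohort,
        truth=truth,
        peptides=peptides,
        sequences=sequences,
        protein_truth=protein_truth,
        phospho=phospho,
        mutations=mutations,
        segments=segments,
        arms=arms,
        signatures=signatures,
        gene_sets=gene_sets,
        config=config,
    )
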