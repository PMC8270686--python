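"""Synthetic four-group expression datasets with planted ground truth.

The generator emulates the structure of a four-group microarray study of
thyroid development: adult thyroid (AT), embryonic thyroid (ET), an adult
multi-tissue mix (AM) and an embryonic multi-tissue mix (EM).  It plants
gene classes whose signed log2 effects across the four group contrasts
(comp1 = AT-ET, comp2 = AT-AM, comp3 = AM-EM, comp4 = ET-EM) reproduce the
qualitative expression programs the analysis is designed to detect:

``thyroid_identity``
    high in both thyroids relative to both mixes, flat in development
    (comp1 = comp3 = 0, comp4 = +e; hence comp2 = +e);
``shared_developmental``
    up in adults versus embryos in thyroid and non-thyroid tissue alike
    (comp1 = comp3 = +e, comp4 = 0);
``pattern_I`` .. ``pattern_IV``
    the four developmental programs defined over comparisons 1, 3, 4
    (differentiation-factor-like, transcription-factor-like,
    transient-regulator-like, maturation-factor-like);
``at_specific`` / ``et_specific``
    enriched in one thyroid only (comp2 resp. comp4 up, the other not);
``null``
    all four effects exactly zero.

Only three of the four contrasts are free: the group means force
comp2 = comp1 + comp4 - comp3, and the generator parameterizes classes by
(comp1, comp3, comp4) and derives comp2.

Expression model: probe intensity = gene baseline + probe affinity offset
+ group effect (+ a zero-mean within-ET gestational-stage trend for
developmentally regulated and identity genes) + N(0, sigma_g^2), with
gene-wise variances
sigma_g^2 drawn from a scaled-inverse-chi-square(d0, s0^2) prior -- the
same family the moderated-t empirical-Bayes fit assumes, so the shrinkage
target of the downstream fit is analytically known.  Probes of a gene form
one probeset; affinity offsets are N(0, 0.5^2) and constant across
samples, so median-polish summarization must remove them.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, ProbeAnnotation, GROUPS

CLASS_NAMES = (
    "thyroid_identity",
    "shared_developmental",
    "pattern_I",
    "pattern_II",
    "pattern_III",
    "pattern_IV",
    "at_specific",
    "et_specific",
)

#: engineered QC violations, cycled over the bad arrays
BAD_ARRAY_RULES = ("rle_median", "nuse_median", "spike_order")

PROBE_AFFINITY_SD = 0.5
STAGE_WEEKS_RANGE = (7.0, 11.0)
#: tissue-identity genes carry much larger fold changes than ordinary
#: regulated genes (hallmark thyroid genes reach several hundred-fold);
#: their planted magnitudes are drawn from effect_range scaled by this factor
IDENTITY_EFFECT_SCALE = 2.0
#: fraction of a gene's adult-vs-embryonic difference traversed within the
#: simulated gestational window.  Thyroid functional differentiation takes
#: place within weeks 7-11, so thyroid developmental-pattern genes traverse
#: most of their course in-window; organism-wide maturation (the shared
#: developmental program) extends through gestation and beyond, so those
#: genes traverse only part of theirs.
STAGE_RAMP_SCALE_THYROID = 0.7
STAGE_RAMP_SCALE_SHARED = 0.1
#: thyroid-identity genes consolidate during the window (functional
#: differentiation: pre-colloid to colloid); each trends with stage around
#: its established level -- approaching it from below or above with equal
#: probability -- with a swing of this fraction of its amplitude
STAGE_RAMP_SCALE_IDENTITY = 0.8


class ConfigError(ValueError):
    """Simulation configuration violates an invariant."""


def _default_class_counts() -> dict[str, int]:
    return {
        "thyroid_identity": 400,
        "shared_developmental": 250,
        "pattern_I": 50,
        "pattern_II": 50,
        "pattern_III": 50,
        "pattern_IV": 50,
        "at_specific": 50,
        "et_specific": 50,
    }


def _default_group_sizes() -> dict[str, int]:
    return {"AT": 5, "ET": 9, "AM": 20, "EM": 9}


@dataclasses.dataclass
class SimulationConfig:
    n_genes: int = 10_000
    probes_per_gene: tuple[int, int] = (1, 3)
    group_sizes: dict[str, int] = dataclasses.field(default_factory=_default_group_sizes)
    baseline_mean: float = 7.0
    baseline_sd: float = 2.0
    variance_prior: tuple[float, float] = (4.0, 0.25)  # (d0, s0sq)
    effect_range: tuple[float, float] = (1.5, 3.0)
    class_counts: dict[str, int] = dataclasses.field(default_factory=_default_class_counts)
    n_bad_arrays: int = 0
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ConfigError("n_genes must be positive")
        lo, hi = self.probes_per_gene
        if not (1 <= lo <= hi):
            raise ConfigError("probes_per_gene must be an increasing range with lower bound >= 1")
        for g in GROUPS:
            if self.group_sizes.get(g, 0) < 2:
                raise ConfigError(f"group {g} needs at least 2 samples")
        unknown = set(self.class_counts) - set(CLASS_NAMES)
        if unknown:
            raise ConfigError(f"unknown gene classes: {sorted(unknown)}")
        if any(c < 0 for c in self.class_counts.values()):
            raise ConfigError("class counts must be non-negative")
        if sum(self.class_counts.values()) > self.n_genes:
            raise ConfigError("sum of class counts exceeds n_genes")
        if self.effect_range[0] < 1.0:
            raise ConfigError(
                "effect_range lower bound must be >= 1 so planted genes exceed "
                "the twofold threshold in expectation"
            )
        if self.effect_range[1] < self.effect_range[0]:
            raise ConfigError("effect_range must be non-decreasing")
        d0, s0sq = self.variance_prior
        if d0 <= 0 or s0sq <= 0:
            raise ConfigError("variance prior parameters must be positive")
        if self.n_bad_arrays < 0:
            raise ConfigError("n_bad_arrays must be non-negative")
        if self.n_bad_arrays > max(0, self.group_sizes.get("AM", 0) - 2):
            raise ConfigError("bad arrays are drawn from AM and must leave >= 2 clean samples")


@dataclasses.dataclass
class SimulatedDataset:
    matrix: ExpressionMatrix          # probe level, log2
    samples: pd.DataFrame             # index sample_id; group, stage_weeks
    annotation: ProbeAnnotation       # probe -> gene symbol
    truth: pd.DataFrame               # index gene; class, effects, true_pattern
    qc_records: pd.DataFrame          # per-sample QC metric table
    bad_arrays: dict[str, str]        # sample_id -> engineered rule


# ---------------------------------------------------------------------------
# class effect signatures
# ---------------------------------------------------------------------------


def _class_effects(cls: str, e: float, down: bool) -> tuple[float, float, float]:
    """(comp1, comp3, comp4) for one planted gene.

    ``e`` is the drawn effect magnitude; ``down`` selects, for the pattern
    classes, whether the non-thyroid comparison-3 course is planted as a
    genuine down-regulation (-e) or as exactly flat (0) -- both satisfy
    the "downregulated or not differentially expressed" arm of the pattern
    definitions.
    """
    d = -e if down else 0.0
    if cls == "thyroid_identity":
        return (0.0, 0.0, e)
    if cls == "shared_developmental":
        return (e, e, 0.0)
    if cls == "pattern_I":
        return (e, d, e)
    if cls == "pattern_II":
        return (0.0, d, e)
    if cls == "pattern_III":
        return (-e, d, e)
    if cls == "pattern_IV":
        return (e, d, 0.0)
    if cls == "at_specific":
        return (0.0, -e, 0.0)   # comp2 = +e, comp4 = 0
    if cls == "et_specific":
        return (0.0, e, e)      # comp2 = 0, comp4 = +e
    return (0.0, 0.0, 0.0)      # null


def true_pattern(comp1: float, comp3: float, comp4: float,
                 threshold: float = 1.0) -> str:
    """Pattern implied by planted effects under the comparison-1/3/4 rules.

    A planted effect >= +threshold counts as truly up, <= -threshold truly
    down, exactly 0 truly unchanged; anything else matches no pattern.
    """
    def s(x: float) -> str:
        if x >= threshold:
            return "UP"
        if x <= -threshold:
            return "DOWN"
        if x == 0.0:
            return "FLAT"
        return "AMBIGUOUS"

    s1, s3, s4 = s(comp1), s(comp3), s(comp4)
    if s3 in ("DOWN", "FLAT"):
        if s4 == "UP":
            if s1 == "UP":
                return "I"
            if s1 == "FLAT":
                return "II"
            if s1 == "DOWN":
                return "III"
        if s4 == "FLAT" and s1 == "UP":
            return "IV"
    return "NONE"


# ---------------------------------------------------------------------------
# generator
# ---------------------------------------------------------------------------


def generate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Generate a probe-level four-group dataset with planted ground truth.

    Identical seeds give bit-identical outputs.  Bad arrays (if requested)
    are the last ``n_bad_arrays`` AM samples, each violating exactly one QC
    rule: a +1 log2 global intensity shift (RLE), doubled residual noise
    (NUSE), or an out-of-order spike-in quartet (spike_order), cycled in
    that order.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_genes = config.n_genes
    d0, s0sq = config.variance_prior

    genes = np.array([f"G{i:05d}" for i in range(n_genes)])
    classes = np.full(n_genes, "null", dtype=object)
    pos = 0
    for cls in CLASS_NAMES:
        k = config.class_counts.get(cls, 0)
        classes[pos:pos + k] = cls
        pos += k

    lo, hi = config.effect_range
    magnitudes = rng.uniform(lo, hi, size=n_genes)
    down_flags = rng.random(n_genes) < 0.5
    eff = np.zeros((n_genes, 3))
    magnitudes = np.where(classes == "thyroid_identity",
                          magnitudes * IDENTITY_EFFECT_SCALE, magnitudes)
    for i in range(n_genes):
        if classes[i] != "null":
            eff[i] = _class_effects(classes[i], magnitudes[i], bool(down_flags[i]))
    comp1, comp3, comp4 = eff[:, 0], eff[:, 1], eff[:, 2]
    comp2 = comp1 + comp4 - comp3  # forced by the four group means

    # group means relative to EM = 0
    group_mean = {
        "EM": np.zeros(n_genes),
        "ET": comp4,
        "AM": comp3,
        "AT": comp1 + comp4,
    }

    # samples
    sample_ids: list[str] = []
    sample_groups: list[str] = []
    for g in GROUPS:
        for j in range(config.group_sizes[g]):
            sample_ids.append(f"{g}{j + 1:02d}")
            sample_groups.append(g)
    n_samples = len(sample_ids)
    samples = pd.DataFrame({"group": sample_groups}, index=pd.Index(sample_ids, name="sample_id"))
    samples["stage_weeks"] = np.nan
    et_ids = [s for s, g in zip(sample_ids, sample_groups) if g == "ET"]
    stage = np.linspace(*STAGE_WEEKS_RANGE, num=len(et_ids))
    samples.loc[et_ids, "stage_weeks"] = stage

    # gene-wise variances: scaled-inverse-chi-square(d0, s0sq)
    sigma2 = d0 * s0sq / rng.chisquare(d0, size=n_genes)
    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=n_genes)

    # probes
    plo, phi = config.probes_per_gene
    probes_per_gene = rng.integers(plo, phi + 1, size=n_genes)
    probe_gene_idx = np.repeat(np.arange(n_genes), probes_per_gene)
    probe_ids = []
    for gi, k in zip(range(n_genes), probes_per_gene):
        for j in range(k):
            probe_ids.append(f"{genes[gi]}_p{j + 1}")
    n_probes = len(probe_ids)
    affinity = rng.normal(0.0, PROBE_AFFINITY_SD, size=n_probes)

    # mean matrix: baseline + affinity + group effect (+ ET stage ramp)
    mean = np.empty((n_probes, n_samples))
    group_arr = np.array(sample_groups)
    for g in GROUPS:
        cols = group_arr == g
        mean[:, cols] = (baseline[probe_gene_idx] + affinity)[:, None] \
            + group_mean[g][probe_gene_idx][:, None]

    # within-ET gestational-stage ramp: genes regulated across thyroid
    # development (comp1 != 0) drift toward their adult-thyroid level as
    # gestational age increases, at a class-dependent fraction of the full
    # adult-embryonic difference
    et_cols = np.flatnonzero(group_arr == "ET")
    u = (stage - stage.mean()) / (stage.max() - stage.min())  # in [-0.5, 0.5], zero mean
    ramp_scale = np.select(
        [classes == "shared_developmental",
         np.isin(classes, ("pattern_I", "pattern_III", "pattern_IV"))],
        [STAGE_RAMP_SCALE_SHARED, STAGE_RAMP_SCALE_THYROID],
        default=0.0,
    )
    ramp = ramp_scale * comp1
    # identity genes trend with stage around their (flat) AT-equal level,
    # half rising and half settling with age; comp1 stays 0 in group means
    # because the trend is zero-mean over ET
    identity_sign = np.where(down_flags, -1.0, 1.0)
    ramp = np.where(classes == "thyroid_identity",
                    STAGE_RAMP_SCALE_IDENTITY * magnitudes * identity_sign, ramp)
    mean[:, et_cols] += np.outer(ramp[probe_gene_idx], u)

    noise = rng.normal(0.0, 1.0, size=(n_probes, n_samples)) * np.sqrt(sigma2[probe_gene_idx])[:, None]

    # engineered bad arrays: last AM samples, one rule each
    bad_arrays: dict[str, str] = {}
    am_ids = [s for s, g in zip(sample_ids, sample_groups) if g == "AM"]
    for j in range(config.n_bad_arrays):
        sid = am_ids[-(j + 1)]
        rule = BAD_ARRAY_RULES[j % len(BAD_ARRAY_RULES)]
        bad_arrays[sid] = rule
        col = sample_ids.index(sid)
        if rule == "rle_median":
            mean[:, col] += 1.0
        elif rule == "nuse_median":
            noise[:, col] *= 2.0

    values = pd.DataFrame(mean + noise, index=pd.Index(probe_ids, name="feature_id"),
                          columns=sample_ids)
    matrix = ExpressionMatrix(values, level="probe")
    annotation = ProbeAnnotation({p: genes[gi] for p, gi in zip(probe_ids, probe_gene_idx)})

    truth = pd.DataFrame(
        {
            "class": classes,
            "effect_comp1": comp1,
            "effect_comp2": comp2,
            "effect_comp3": comp3,
            "effect_comp4": comp4,
            "sigma2": sigma2,
        },
        index=pd.Index(genes, name="gene_symbol"),
    )
    truth["true_pattern"] = [
        true_pattern(a, b, c) for a, b, c in zip(comp1, comp3, comp4)
    ]

    qc_records = _generate_qc_records(rng, sample_ids, bad_arrays)
    return SimulatedDataset(matrix, samples, annotation, truth, qc_records, bad_arrays)


def _generate_qc_records(rng: np.random.Generator, sample_ids: list[str],
                         bad_arrays: dict[str, str]) -> pd.DataFrame:
    """Per-array scanner QC metrics, all within the passing windows except
    that spike-order bad arrays get a swapped bioB/bioC pair."""
    n = len(sample_ids)
    bio_b = rng.uniform(6.0, 7.0, n)
    steps = rng.uniform(0.5, 1.5, size=(n, 3))
    quartet = np.column_stack([bio_b, bio_b + steps[:, 0],
                               bio_b + steps[:, 0] + steps[:, 1],
                               bio_b + steps[:, 0] + steps[:, 1] + steps[:, 2]])
    records = pd.DataFrame(
        {
            "bioB": quartet[:, 0],
            "bioC": quartet[:, 1],
            "bioD": quartet[:, 2],
            "cre": quartet[:, 3],
            "maxbg": rng.uniform(100.0, 180.0, n),
            "pp": rng.uniform(40.0, 60.0, n),
            "sf": rng.uniform(0.5, 3.0, n),
            "actin_ratio": rng.uniform(1.0, 4.0, n),
            "gapdh_ratio": rng.uniform(1.0, 3.0, n),
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    for sid, rule in bad_arrays.items():
        if rule == "spike_order":
            b, c = records.loc[sid, "bioB"], records.loc[sid, "bioC"]
            records.loc[sid, "bioB"], records.loc[sid, "bioC"] = c, b
    return records


# ---------------------------------------------------------------------------
# qPCR panel
# ---------------------------------------------------------------------------


def generate_qpcr_panel(
    truth: pd.DataFrame,
    targets: list[str],
    refs: tuple[str, str],
    groups: tuple[str, str] = ("ET", "AT"),
    comparison: str | None = None,
    n_per_group: int = 3,
    base_ct: float = 25.0,
    ref_cts: tuple[float, float] = (20.0, 22.0),
) -> tuple[pd.DataFrame, list[str]]:
    """Construct an idealized Ct table whose ddCt reproduces planted effects.

    The first-named group plays the sample role, the second the calibrator.
    For a target with planted effect ``e`` on the matching comparison the
    sample-group Ct is lowered by ``e`` cycles (Ct drops one cycle per
    doubling), so relative expression after ddCt normalization equals
    ``2**e``.  Reference genes get constant Ct; a reference with a planted
    nonzero effect is reported as a warning rather than honoured.

    Returns the long-format Ct table (sample, group, gene, replicate, ct)
    and the list of warnings.
    """
    warnings: list[str] = []
    if comparison is None:
        pair_to_comp = {("AT", "ET"): "comp1", ("AT", "AM"): "comp2",
                        ("AM", "EM"): "comp3", ("ET", "EM"): "comp4"}
        comparison = (pair_to_comp.get(tuple(groups))
                      or pair_to_comp.get(tuple(reversed(groups))))
        if comparison is None:
            raise ValueError(f"no canonical comparison for groups {groups}; pass comparison=")
    effect_col = f"effect_{comparison}"
    for gene in list(targets) + list(refs):
        if gene not in truth.index:
            raise KeyError(f"gene {gene!r} not present in truth table")
    for ref in refs:
        e = float(truth.loc[ref, effect_col])
        if e != 0.0:
            warnings.append(f"reference gene {ref} has planted {comparison} effect {e:g}")

    # sign convention: groups = (sample_group, calibrator_group); the planted
    # effect is first-named-minus-second for the canonical comparison, so the
    # effect seen by (sample - calibrator) may need flipping
    comp_pair = {"comp1": ("AT", "ET"), "comp2": ("AT", "AM"),
                 "comp3": ("AM", "EM"), "comp4": ("ET", "EM")}[comparison]
    flip = -1.0 if tuple(groups) == tuple(reversed(comp_pair)) else 1.0

    rows = []
    for gi, group in enumerate(groups):
        is_sample_group = gi == 0
        for j in range(n_per_group):
            sid = f"{group}{j + 1:02d}"
            for gene in targets:
                e = flip * float(truth.loc[gene, effect_col])
                ct = base_ct - (e if is_sample_group else 0.0)
                for rep in (1, 2):
                    rows.append((sid, group, gene, rep, ct))
            for ref, rc in zip(refs, ref_cts):
                for rep in (1, 2):
                    rows.append((sid, group, ref, rep, rc))
    table = pd.DataFrame(rows, columns=["sample_id", "group", "gene", "replicate", "ct"])
    return table, warnings
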