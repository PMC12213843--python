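"""Synthetic low-risk pregnancy cohorts and maternal-plasma read-count simulation.

The generator emulates the statistical structure a cfDNA screening analysis
sees:

* true fetal karyotype states drawn at configured category prevalences
  (common trisomies, sex-chromosome aneuploidies, rare autosomal aneuploidies,
  sub-chromosomal CNVs, remainder euploid);
* a *placental* karyotype that usually equals the fetal one but can be
  discordant — confined placental mosaicism (CPM) — which is the biological
  engine of screening false positives and false negatives, since plasma cfDNA
  reports the placenta, not the fetus;
* a fetal fraction (FF) drawn from a truncated lognormal concentrated in the
  5–16% band, with a quality-control redraw below 3.5%;
* per-chromosome (and on demand per-bin) unique-read counts drawn
  multinomially around a dosage-mixture expectation: the maternal compartment
  contributes ``1 - FF`` at euploid female dosage and the placental
  compartment contributes ``FF`` with the state's copy numbers applied at its
  mosaic fraction;
* the post-call cascade of invasive confirmation, refusal, and pregnancy
  outcome.

All randomness flows through one ``numpy.random.Generator`` per operation, so
every draw is bitwise reproducible from its seed.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import yaml
from scipy import stats

from .genome_reference import (
    AUTOSOMES,
    ChromosomeMap,
    CountProfile,
)

__all__ = [
    "KaryotypeState",
    "SimulatedCase",
    "OutcomeRecord",
    "GenomeBaseline",
    "CohortConfig",
    "FollowupConfig",
    "sample_cohort",
    "expected_proportions",
    "simulate_counts",
    "simulate_followup",
    "category_group",
    "CountProfile",
]

CATEGORIES = ("EUPLOID", "T21", "T18", "T13", "XO", "XXX", "XXY", "XYY", "RAA", "CNV")
SCA_CATEGORIES = ("XO", "XXX", "XXY", "XYY")
COMMON_TRISOMIES = ("T21", "T18", "T13")

_TRISOMY_CHROM = {"T21": "chr21", "T18": "chr18", "T13": "chr13"}


def category_group(category: str) -> str:
    """Collapse a call/truth category to the reporting group used in outcome tables."""
    if category in COMMON_TRISOMIES:
        return "common_trisomy"
    if category in SCA_CATEGORIES:
        return "SCA"
    if category in ("RAA", "CNV", "EUPLOID"):
        return category
    raise ValueError(f"unknown category {category!r}")


@dataclass(frozen=True)
class KaryotypeState:
    """One (possibly mosaic) chromosomal state of a tissue.

    ``mosaic_fraction`` is the fraction of the tissue carrying the
    abnormality; 1.0 means non-mosaic. Only the fields of the active category
    may be set.
    """

    category: str
    raa_chrom: str | None = None
    raa_kind: Literal["trisomy", "monosomy"] | None = None
    cnv_segment: tuple[str, int, int, int] | None = None  # (chrom, start, end, cn)
    mosaic_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if not (0.0 < self.mosaic_fraction <= 1.0):
            raise ValueError("mosaic_fraction must be in (0, 1]")
        if self.category == "RAA":
            if self.raa_chrom is None or self.raa_kind is None:
                raise ValueError("RAA state needs raa_chrom and raa_kind")
            if self.raa_chrom not in AUTOSOMES:
                raise ValueError(f"RAA chromosome {self.raa_chrom!r} is not an autosome")
        elif self.raa_chrom is not None or self.raa_kind is not None:
            raise ValueError("raa_* fields only valid for RAA states")
        if self.category == "CNV":
            if self.cnv_segment is None:
                raise ValueError("CNV state needs cnv_segment")
            chrom, start, end, cn = self.cnv_segment
            if end <= start or start < 0:
                raise ValueError("CNV segment must have positive length")
            if cn not in (1, 3):
                raise ValueError("CNV copy number must be 1 (del) or 3 (dup)")
        elif self.cnv_segment is not None:
            raise ValueError("cnv_segment only valid for CNV states")

    # -- convenience constructors ------------------------------------------
    @classmethod
    def euploid(cls) -> "KaryotypeState":
        return cls("EUPLOID")

    @property
    def is_abnormal(self) -> bool:
        return self.category != "EUPLOID"

    @property
    def forced_sex(self) -> str | None:
        if self.category in ("XO", "XXX"):
            return "female"
        if self.category in ("XXY", "XYY"):
            return "male"
        return None

    # -- compact string codes (cohort TSV) ---------------------------------
    def to_string(self) -> str:
        m = self.mosaic_fraction
        if self.category == "RAA":
            return f"RAA:{self.raa_chrom}:{self.raa_kind}:m={m:g}"
        if self.category == "CNV":
            chrom, start, end, cn = self.cnv_segment
            return f"CNV:{chrom}:{start}-{end}:cn={cn}:m={m:g}"
        if m < 1.0:
            return f"{self.category}:m={m:g}"
        return self.category

    @classmethod
    def from_string(cls, code: str) -> "KaryotypeState":
        parts = code.split(":")
        cat = parts[0]
        m = 1.0
        if parts and parts[-1].startswith("m="):
            m = float(parts[-1][2:])
            parts = parts[:-1]
        if cat == "RAA":
            _, chrom, kind = parts
            return cls("RAA", raa_chrom=chrom, raa_kind=kind, mosaic_fraction=m)
        if cat == "CNV":
            _, chrom, span, cn_part = parts
            start, _, end = span.partition("-")
            cn = int(cn_part.removeprefix("cn="))
            return cls(
                "CNV", cnv_segment=(chrom, int(start), int(end), cn), mosaic_fraction=m
            )
        return cls(cat, mosaic_fraction=m)


@dataclass
class SimulatedCase:
    """One pregnancy: demographics, true fetal/placental states, fetal fraction."""

    case_id: str
    maternal_age: float
    gestational_age: float
    fetal_sex: Literal["female", "male"]
    fetal_state: KaryotypeState
    placental_state: KaryotypeState
    fetal_fraction: float
    redraw_flag: bool = False


@dataclass
class OutcomeRecord:
    """Confirmatory-diagnosis and pregnancy-outcome endpoint of one screened case."""

    case_id: str
    amniocentesis: Literal["accepted", "refused", "not_applicable"]
    confirmed: Literal["true_positive", "false_positive", "not_applicable"]
    outcome: Literal["termination", "stillbirth", "livebirth"]


# ---------------------------------------------------------------------------
# Dosage baseline
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomeBaseline:
    """Expected euploid read-proportion structure of maternal plasma.

    The maternal compartment is a euploid female genome, so the baseline
    proportion of chromosome N is its length share of the diploid female
    genome, less a small constant chrY background (``chry_background``) that
    stands for reads mismapped to chrY in any sample. A single fetal Y
    chromosome contributes ``chry_single_copy_weight`` — its length share
    scaled by an effective-mappability factor, because unique chrY coverage is
    far below its nominal length.
    """

    cmap: ChromosomeMap
    chrom_female: np.ndarray  # per-chromosome euploid female proportions, sums to 1
    chry_single_copy_weight: float
    chry_background: float

    @classmethod
    def from_map(
        cls,
        cmap: ChromosomeMap,
        chry_background: float = 2e-4,
        chry_effective_fraction: float = 0.4,
    ) -> "GenomeBaseline":
        lengths = np.asarray(cmap.lengths, dtype=float)
        y = cmap.chrom_index["chrY"]
        non_y_len = lengths.sum() - lengths[y]
        p = lengths / non_y_len * (1.0 - chry_background)
        p[y] = chry_background
        yw = chry_effective_fraction * (lengths[y] / non_y_len) * (1.0 - chry_background) / 2.0
        return cls(
            cmap=cmap,
            chrom_female=p,
            chry_single_copy_weight=yw,
            chry_background=chry_background,
        )

    @property
    def x_index(self) -> int:
        return self.cmap.chrom_index["chrX"]

    @property
    def y_index(self) -> int:
        return self.cmap.chrom_index["chrY"]

    @property
    def male_chry_proportion(self) -> float:
        """chrY read share of a pure (FF=1) male placental genome."""
        f = self.chrom_female
        yw = self.chry_single_copy_weight
        s = 1.0 - f[self.x_index] / 2.0 + yw
        return float((f[self.y_index] + yw) / s)

    def bin_baseline(self) -> np.ndarray:
        """Euploid female per-bin proportions (bins share their chromosome's
        proportion in proportion to bin width)."""
        cmap = self.cmap
        lengths = np.asarray(cmap.lengths, dtype=float)
        per_bin = (
            self.chrom_female[cmap.bin_chroms]
            * cmap.bin_widths
            / lengths[cmap.bin_chroms]
        )
        return per_bin


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


class ConfigError(ValueError):
    """A cohort or follow-up configuration violates its documented bounds."""


#: chromosomes eligible for rare autosomal aneuploidies: autosomes other than
#: the common-trisomy targets, excluding chr1 and chr19 (never observed).
RAA_CHROM_POOL: tuple[str, ...] = tuple(
    c for c in AUTOSOMES if c not in ("chr1", "chr19", "chr13", "chr18", "chr21")
)


@dataclass
class CohortConfig:
    """Generator settings; defaults encode the study conditions being emulated.

    Prevalences are per-pregnancy probabilities of the *fetal* state
    (remainder euploid). ``cpm_fp_rate`` is the probability that a euploid
    fetus carries a discordant abnormal placental line; ``cpm_fp_weights``
    spreads it over categories in proportion to the observed false-positive
    mix. ``cpm_fn_rate`` is the probability that an abnormal fetus has a
    euploid placenta (driving false negatives).
    """

    # category prevalences
    prev_t21: float = 0.0005
    prev_t18: float = 0.0001
    prev_t13: float = 0.0003
    prev_sca: float = 0.0041
    prev_raa: float = 0.0015
    prev_cnv: float = 0.0008
    # SCA subtype mix (positive-call composition: XO 150, XXX 55, XXY 77, XYY 52)
    sca_weights: dict[str, float] = field(
        default_factory=lambda: {"XO": 150, "XXX": 55, "XXY": 77, "XYY": 52}
    )
    # demographics (truncated normals)
    maternal_age_mean: float = 29.6
    maternal_age_sd: float = 3.5
    maternal_age_range: tuple[float, float] = (18.0, 34.0)
    gestational_age_mean: float = 15.4
    gestational_age_sd: float = 2.0
    gestational_age_range: tuple[float, float] = (11.0, 23.0)
    # fetal fraction: lognormal(median, sigma) truncated to ff_bounds;
    # ~85% of mass in the 5-16% band, ~0.8% below the 3.5% QC cutoff
    ff_median: float = 0.092
    ff_sigma: float = 0.40
    ff_bounds: tuple[float, float] = (0.005, 0.40)
    qc_ff_threshold: float = 0.035
    # confined placental mosaicism
    cpm_fp_rate: float = 0.0043
    cpm_fn_rate: float = 0.006
    cpm_mosaic_range: tuple[float, float] = (0.2, 0.8)
    cpm_fp_weights: dict[str, float] = field(
        default_factory=lambda: {
            "T21": 5, "T18": 4, "T13": 15, "XO": 97, "XXX": 19,
            "XXY": 10, "XYY": 9, "RAA": 81, "CNV": 20,
        }
    )
    # RAA truth model: mostly mosaic trisomies
    raa_mosaic_range: tuple[float, float] = (0.1, 1.0)
    raa_monosomy_prob: float = 0.0246
    # CNV truth model: ~80% of segments > 5 Mb, duplications 58%
    cnv_large_prob: float = 0.8
    cnv_size_large: tuple[float, float] = (5e6, 20e6)
    cnv_size_small: tuple[float, float] = (1e6, 5e6)
    cnv_dup_prob: float = 0.58

    def __post_init__(self) -> None:
        if self.total_prevalence >= 1.0:
            raise ConfigError("category prevalences must sum to < 1")
        for name in (
            "prev_t21", "prev_t18", "prev_t13", "prev_sca", "prev_raa", "prev_cnv",
            "cpm_fp_rate", "cpm_fn_rate",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must be a probability, got {v}")
        lo, hi = self.ff_bounds
        if not (0.0 < lo < hi < 1.0):
            raise ConfigError("ff_bounds must satisfy 0 < low < high < 1")

    @property
    def total_prevalence(self) -> float:
        return (
            self.prev_t21 + self.prev_t18 + self.prev_t13
            + self.prev_sca + self.prev_raa + self.prev_cnv
        )

    def category_probs(self) -> dict[str, float]:
        return {
            "T21": self.prev_t21,
            "T18": self.prev_t18,
            "T13": self.prev_t13,
            "SCA": self.prev_sca,
            "RAA": self.prev_raa,
            "CNV": self.prev_cnv,
        }

    # -- YAML round trip ----------------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        for key, value in data.items():
            if isinstance(value, tuple):
                data[key] = list(value)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        valid = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        unknown = set(data) - valid
        if unknown:
            raise ConfigError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        for key, value in data.items():
            if isinstance(value, list):
                data[key] = tuple(value)
        return cls(**data)


@dataclass
class FollowupConfig:
    """Confirmatory-diagnosis uptake and outcome probabilities.

    Termination probabilities apply to confirmed true positives by category
    group; confirmed false positives deliver at ``fp_delivery`` with the
    residual split evenly between termination and stillbirth. Refusals follow
    the observed refusal-group outcome mix.
    """

    uptake: float = 0.9565
    termination_tp: dict[str, float] = field(
        default_factory=lambda: {
            "common_trisomy": 1.0, "SCA": 0.7807, "RAA": 0.7949, "CNV": 0.6739,
        }
    )
    stillbirth_tp: float = 0.0
    fp_delivery: float = 0.9890
    refuse_termination: float = 0.3077
    refuse_stillbirth: float = 0.0385
    #: probability that a refusal is still resolved by postnatal testing
    #: (16 of 26 refusals in the emulated cohort); unresolved refusals are
    #: excluded from performance denominators
    refuse_postnatal_test: float = 0.6154

    def __post_init__(self) -> None:
        probs = [self.uptake, self.stillbirth_tp, self.fp_delivery,
                 self.refuse_termination, self.refuse_stillbirth,
                 *self.termination_tp.values()]
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ConfigError("all follow-up probabilities must lie in [0, 1]")


# ---------------------------------------------------------------------------
# Cohort sampling
# ---------------------------------------------------------------------------


def _draw_truncnorm(
    rng: np.random.Generator, mean: float, sd: float, bounds: tuple[float, float], n: int
) -> np.ndarray:
    """Truncated normal draws whose *truncated* mean equals ``mean``.

    The underlying normal's location is solved so that truncation at the
    configured range does not shift the targeted mean.
    """
    from scipy.optimize import brentq

    def truncated_mean_error(loc: float) -> float:
        a, b = (bounds[0] - loc) / sd, (bounds[1] - loc) / sd
        return stats.truncnorm.mean(a, b, loc=loc, scale=sd) - mean

    loc = brentq(truncated_mean_error, mean - 5 * sd, mean + 5 * sd)
    a, b = (bounds[0] - loc) / sd, (bounds[1] - loc) / sd
    return stats.truncnorm.rvs(a, b, loc=loc, scale=sd, size=n, random_state=rng)


def draw_fetal_fractions(config: CohortConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    """Truncated lognormal FF draws (rejection sampling within ff_bounds)."""
    mu = math.log(config.ff_median)
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.lognormal(mu, config.ff_sigma, size=2 * (n - filled) + 16)
        keep = draw[(draw >= config.ff_bounds[0]) & (draw <= config.ff_bounds[1])]
        take = min(len(keep), n - filled)
        out[filled : filled + take] = keep[:take]
        filled += take
    return out


def _draw_cnv_state(
    config: CohortConfig,
    cmap: ChromosomeMap,
    rng: np.random.Generator,
    mosaic: float = 1.0,
) -> KaryotypeState:
    chrom = AUTOSOMES[rng.integers(len(AUTOSOMES))]
    length = cmap.lengths[cmap.chrom_index[chrom]]
    if rng.random() < config.cnv_large_prob:
        size = rng.uniform(*config.cnv_size_large)
    else:
        size = rng.uniform(*config.cnv_size_small)
    size = int(min(size, 0.9 * length))
    start = int(rng.integers(0, length - size))
    cn = 3 if rng.random() < config.cnv_dup_prob else 1
    return KaryotypeState(
        "CNV", cnv_segment=(chrom, start, start + size, cn), mosaic_fraction=mosaic
    )


def _draw_abnormal_state(
    category: str,
    config: CohortConfig,
    cmap: ChromosomeMap,
    rng: np.random.Generator,
) -> KaryotypeState:
    if category in COMMON_TRISOMIES:
        return KaryotypeState(category)
    if category == "SCA":
        names = list(config.sca_weights)
        w = np.array([config.sca_weights[k] for k in names], dtype=float)
        sub = names[rng.choice(len(names), p=w / w.sum())]
        return KaryotypeState(sub)
    if category == "RAA":
        chrom = RAA_CHROM_POOL[rng.integers(len(RAA_CHROM_POOL))]
        kind = "monosomy" if rng.random() < config.raa_monosomy_prob else "trisomy"
        m = rng.uniform(*config.raa_mosaic_range)
        return KaryotypeState("RAA", raa_chrom=chrom, raa_kind=kind, mosaic_fraction=m)
    if category == "CNV":
        return _draw_cnv_state(config, cmap, rng)
    raise ValueError(f"not an abnormal category: {category}")


def _draw_cpm_state(
    fetal_sex: str,
    config: CohortConfig,
    cmap: ChromosomeMap,
    rng: np.random.Generator,
) -> KaryotypeState:
    """Abnormal placental line over a euploid fetus, sex-compatible."""
    names = list(config.cpm_fp_weights)
    w = np.array([config.cpm_fp_weights[k] for k in names], dtype=float)
    p = w / w.sum()
    while True:
        cat = names[rng.choice(len(names), p=p)]
        forced = KaryotypeState(cat).forced_sex if cat in SCA_CATEGORIES else None
        if forced is None or forced == fetal_sex:
            break
    m = rng.uniform(*config.cpm_mosaic_range)
    if cat == "RAA":
        chrom = RAA_CHROM_POOL[rng.integers(len(RAA_CHROM_POOL))]
        return KaryotypeState("RAA", raa_chrom=chrom, raa_kind="trisomy", mosaic_fraction=m)
    if cat == "CNV":
        return _draw_cnv_state(config, cmap, rng, mosaic=m)
    return KaryotypeState(cat, mosaic_fraction=m)


def sample_cohort(
    config: CohortConfig,
    n: int,
    seed: int | np.random.Generator,
    cmap: ChromosomeMap | None = None,
) -> list[SimulatedCase]:
    """Draw a cohort of ``n`` pregnancies.

    Fetal state comes from the configured prevalences; sex is a fair
    Bernoulli unless the state forces it; demographics come from truncated
    normals; FF from the truncated lognormal with one QC redraw below the
    3.5% cutoff; the placental state equals the fetal one except for the CPM
    discordance channels.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cmap = cmap or ChromosomeMap.grch37()

    cat_probs = config.category_probs()
    names = list(cat_probs) + ["EUPLOID"]
    p = np.array([*cat_probs.values(), 1.0 - config.total_prevalence])
    cat_idx = rng.choice(len(names), size=n, p=p)
    ages = _draw_truncnorm(rng, config.maternal_age_mean, config.maternal_age_sd,
                           config.maternal_age_range, n)
    gests = _draw_truncnorm(rng, config.gestational_age_mean, config.gestational_age_sd,
                            config.gestational_age_range, n)
    ffs = draw_fetal_fractions(config, n, rng)
    sex_draws = rng.random(n)
    cpm_fp_draws = rng.random(n)
    cpm_fn_draws = rng.random(n)

    cases: list[SimulatedCase] = []
    for i in range(n):
        category = names[cat_idx[i]]
        if category == "EUPLOID":
            fetal = KaryotypeState.euploid()
        else:
            fetal = _draw_abnormal_state(category, config, cmap, rng)
        sex = fetal.forced_sex or ("male" if sex_draws[i] < 0.5 else "female")

        if fetal.is_abnormal:
            placental = (
                KaryotypeState.euploid()
                if cpm_fn_draws[i] < config.cpm_fn_rate
                else fetal
            )
        else:
            placental = (
                _draw_cpm_state(sex, config, cmap, rng)
                if cpm_fp_draws[i] < config.cpm_fp_rate
                else fetal
            )

        ff = float(ffs[i])
        redraw = ff < config.qc_ff_threshold
        if redraw:
            ff = float(draw_fetal_fractions(config, 1, rng)[0])

        cases.append(
            SimulatedCase(
                case_id=f"case{i:06d}",
                maternal_age=float(ages[i]),
                gestational_age=float(gests[i]),
                fetal_sex=sex,
                fetal_state=fetal,
                placental_state=placental,
                fetal_fraction=ff,
                redraw_flag=redraw,
            )
        )
    return cases


# ---------------------------------------------------------------------------
# Dosage-mixture expected proportions
# ---------------------------------------------------------------------------


def _copy_ratio_vector(
    state: KaryotypeState, fetal_sex: str, baseline: GenomeBaseline
) -> tuple[np.ndarray, float]:
    """Per-chromosome fetal-to-maternal weight ratios and effective Y copy count.

    The ratio for chromosome N is (effective fetal copies)/2, where the
    effective copy number interpolates the euploid-for-sex value and the
    carrier value by the mosaic fraction. chrY is handled separately since
    the maternal compartment carries none.
    """
    cmap = baseline.cmap
    m = state.mosaic_fraction
    ratios = np.ones(cmap.n_chroms)
    xi = baseline.x_index

    base_x = 2.0 if fetal_sex == "female" else 1.0
    n_y = 0.0 if fetal_sex == "female" else 1.0
    cat = state.category

    if cat in COMMON_TRISOMIES:
        ci = cmap.chrom_index[_TRISOMY_CHROM[cat]]
        ratios[ci] = (2.0 + m) / 2.0
    elif cat == "RAA":
        ci = cmap.chrom_index[state.raa_chrom]
        delta = 1.0 if state.raa_kind == "trisomy" else -1.0
        ratios[ci] = (2.0 + m * delta) / 2.0
    elif cat == "XO":
        base_x = 2.0 - m
    elif cat == "XXX":
        base_x = 2.0 + m
    elif cat == "XXY":
        base_x = 1.0 + m
    elif cat == "XYY":
        n_y = 1.0 + m

    ratios[xi] = base_x / 2.0
    return ratios, n_y


def expected_proportions(
    state: KaryotypeState,
    ff: float,
    baseline: GenomeBaseline,
    fetal_sex: str,
    level: Literal["chrom", "bin"] = "chrom",
) -> np.ndarray:
    """Expected read-proportion vector for a pregnancy.

    Mixture of maternal euploid-female dosage (weight ``1 - ff``) and the
    placental genome's dosage (weight ``ff``), normalized once over the whole
    genome: an affected region with copy number ``c`` at mosaic fraction ``m``
    carries the multiplier ``1 + m * ff * (c - 2) / 2`` before normalization.
    """
    if not (0.0 <= ff < 1.0):
        raise ValueError(f"fetal fraction must lie in [0, 1), got {ff}")
    forced = state.forced_sex
    if forced is not None and forced != fetal_sex:
        raise ValueError(f"{state.category} state requires a {forced} fetus")

    cmap = baseline.cmap
    f = baseline.chrom_female
    yi = baseline.y_index
    ratios, n_y = _copy_ratio_vector(state, fetal_sex, baseline)

    # unnormalized combined weights, chromosome level
    w = f * (1.0 - ff + ff * ratios)
    w[yi] = f[yi] + ff * n_y * baseline.chry_single_copy_weight

    if level == "chrom" and state.category != "CNV":
        return w / w.sum()

    if state.category == "CNV":
        chrom, start, end, cn = state.cnv_segment
        ci = cmap.chrom_index[chrom]
        length = cmap.lengths[ci]
        if end > length:
            raise ValueError("CNV segment extends beyond its chromosome")
        frac = (end - start) / length
        seg_mult = 1.0 + state.mosaic_fraction * ff * (cn - 2) / 2.0
        if level == "chrom":
            w[ci] *= 1.0 - frac + frac * seg_mult
            return w / w.sum()

    # bin level: spread chromosome weights over bins by width, then apply the
    # CNV multiplier to the overlapped portion of each affected bin
    lengths = np.asarray(cmap.lengths, dtype=float)
    wb = w[cmap.bin_chroms] * cmap.bin_widths / lengths[cmap.bin_chroms]
    if state.category == "CNV":
        chrom, start, end, cn = state.cnv_segment
        sl = cmap.bin_slice(chrom)
        overlap = np.clip(
            np.minimum(cmap.bin_ends[sl], end) - np.maximum(cmap.bin_starts[sl], start),
            0,
            None,
        )
        frac_bin = overlap / cmap.bin_widths[sl]
        seg_mult = 1.0 + state.mosaic_fraction * ff * (cn - 2) / 2.0
        wb[sl] = wb[sl] * (1.0 - frac_bin + frac_bin * seg_mult)
    return wb / wb.sum()


def euploid_expected_matrix(
    ffs: np.ndarray, male: np.ndarray, baseline: GenomeBaseline
) -> np.ndarray:
    """Vectorized chromosome-level expectations for euploid pregnancies.

    ``ffs``: (n,) fetal fractions; ``male``: (n,) boolean. Returns (n, 24)
    normalized proportion rows. Equivalent to calling
    :func:`expected_proportions` row by row with a euploid state.
    """
    ffs = np.asarray(ffs, dtype=float)
    male = np.asarray(male, dtype=bool)
    f = baseline.chrom_female
    n = len(ffs)
    w = np.tile(f, (n, 1))
    xi, yi = baseline.x_index, baseline.y_index
    w[male, xi] = f[xi] * (1.0 - ffs[male] / 2.0)
    w[male, yi] = f[yi] + ffs[male] * baseline.chry_single_copy_weight
    return w / w.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# Count simulation
# ---------------------------------------------------------------------------


def simulate_counts(
    expected: np.ndarray,
    total_reads: int,
    seed: int | np.random.Generator,
    cmap: ChromosomeMap | None = None,
) -> CountProfile:
    """Multinomial unique-read counts around an expected proportion vector.

    A 24-long vector yields chromosome-level counts only; a full-length bin
    vector yields bin counts whose chromosome sums are the chromosome counts.
    """
    if total_reads < 1:
        raise ValueError("total_reads must be >= 1")
    expected = np.asarray(expected, dtype=float)
    s = expected.sum()
    if abs(s - 1.0) > 1e-6:
        raise ValueError(f"expected proportions must sum to 1, got {s:.8f}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cmap = cmap or ChromosomeMap.grch37()

    draw = rng.multinomial(total_reads, expected / s)
    if expected.shape == (cmap.n_chroms,):
        return CountProfile(chrom_counts=draw, total=total_reads)
    if expected.shape == (cmap.total_bins,):
        chrom_counts = np.bincount(
            cmap.bin_chroms, weights=draw, minlength=cmap.n_chroms
        ).astype(np.int64)
        return CountProfile(chrom_counts=chrom_counts, total=total_reads, bin_counts=draw)
    raise ValueError(
        f"expected vector of length 24 or {cmap.total_bins}, got {expected.shape}"
    )


def simulate_count_matrix(
    expected_matrix: np.ndarray, total_reads: int, rng: np.random.Generator
) -> np.ndarray:
    """Batched multinomial draws: one row of counts per row of expectations."""
    pm = np.asarray(expected_matrix, dtype=float)
    pm = pm / pm.sum(axis=1, keepdims=True)
    return rng.multinomial(total_reads, pm)


def simulate_reference_profiles(
    n: int,
    sex: Literal["female", "male"],
    config: CohortConfig,
    depth: int,
    rng: np.random.Generator,
    baseline: GenomeBaseline,
    bins: bool = False,
) -> list[CountProfile]:
    """Euploid reference pregnancies of one fetal sex, for panel construction."""
    ffs = draw_fetal_fractions(config, n, rng)
    state = KaryotypeState.euploid()
    out = []
    for ff in ffs:
        level = "bin" if bins else "chrom"
        exp = expected_proportions(state, float(ff), baseline, sex, level=level)
        out.append(simulate_counts(exp, depth, rng, baseline.cmap))
    return out


# ---------------------------------------------------------------------------
# Follow-up cascade
# ---------------------------------------------------------------------------


def simulate_followup(
    call,
    case: SimulatedCase,
    rates: FollowupConfig,
    seed: int | np.random.Generator,
) -> OutcomeRecord:
    """Confirmatory diagnosis and pregnancy outcome for one screened case.

    Negative (or no-call) screens return a live birth without confirmation.
    Positive screens accept amniocentesis with probability ``uptake``;
    accepted cases are adjudicated against the fetal truth, then the outcome
    is drawn from the category-specific termination/delivery probabilities.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    if call is None or call.result != "positive":
        return OutcomeRecord(case.case_id, "not_applicable", "not_applicable", "livebirth")

    from .performance_stats import call_matches_truth  # late import: avoids a cycle

    if rng.random() >= rates.uptake:
        r = rng.random()
        if r < rates.refuse_termination:
            outcome = "termination"
        elif r < rates.refuse_termination + rates.refuse_stillbirth:
            outcome = "stillbirth"
        else:
            outcome = "livebirth"
        if rng.random() < rates.refuse_postnatal_test:
            confirmed = (
                "true_positive"
                if call_matches_truth(call, case.fetal_state)
                else "false_positive"
            )
        else:
            confirmed = "not_applicable"
        return OutcomeRecord(case.case_id, "refused", confirmed, outcome)

    is_tp = call_matches_truth(call, case.fetal_state)
    if is_tp:
        group = category_group(case.fetal_state.category)
        term_p = rates.termination_tp.get(group, 0.0)
        r = rng.random()
        if r < term_p:
            outcome = "termination"
        elif r < term_p + rates.stillbirth_tp:
            outcome = "stillbirth"
        else:
            outcome = "livebirth"
        return OutcomeRecord(case.case_id, "accepted", "true_positive", outcome)

    r = rng.random()
    if r < rates.fp_delivery:
        outcome = "livebirth"
    elif r < rates.fp_delivery + (1.0 - rates.fp_delivery) / 2.0:
        outcome = "termination"
    else:
        outcome = "stillbirth"
    return OutcomeRecord(case.case_id, "accepted", "false_positive", outcome)
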