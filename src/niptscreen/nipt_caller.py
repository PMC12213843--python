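"""Screening computation: z-scores, fetal fraction, QC, and category calls.

The chromosome-dosage statistic is the standard one:

    z_N = (%chrN_test - mean(%chrN_ref)) / sd(%chrN_ref)

with ``%chrN = unique reads on chrN / total unique reads``. A chromosome with
z in the closed interval [-3, 3] is screen-negative; |z| > 3 (strictly) flags
it. chr21/18/13 excesses map to the common trisomies, other autosomes to rare
autosomal aneuploidies (trisomy for positive z, monosomy for negative), and
the sex chromosomes to XO/XXX/XXY/XYY via the dosage rules below. Bin-level
z-scores feed a windowed scan for sub-chromosomal CNVs.

Fetal fraction for a male fetus comes from the chrY read excess over the
female background; the QC cutoff is FF >= 3.5%, with one redraw allowed
before a no-call.

Sex-chromosome call rules
-------------------------
The fetal sex call is a chrY presence test (chrY proportion more than 3
female-panel SDs above the female background). For female fetuses, chrX
dosage is fetal-fraction-invariant (mother and fetus are both 46,XX at
baseline), so plain z_X against the female stratum decides: z_X < -3 -> XO,
z_X > 3 -> XXX. For male fetuses the chrX and chrY proportions both move with
FF, so XXY and XYY are resolved jointly: each candidate karyotype implies a
fetal fraction from the chrY dosage, hence an expected chrX proportion; the
normal male karyotype is rejected when its chrX z exceeds 3, and the better
fitting abnormal candidate is reported. Calls are categorical — no mosaic
fraction is estimated from the z magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, NamedTuple, Sequence

import numpy as np

from .genome_reference import (
    AUTOSOMES,
    ChromosomeMap,
    CountProfile,
    PanelDegeneracyError,
    ReferencePanel,
)
from .synthetic_cohort import GenomeBaseline

__all__ = [
    "CallThresholds",
    "ZScoreResult",
    "CallItem",
    "NIPTCall",
    "CNVCall",
    "QCStateError",
    "compute_z",
    "estimate_ff",
    "qc_check",
    "classify",
    "call_cnv",
    "screen_sample",
]


class QCStateError(RuntimeError):
    """Classification requested on a QC-failed z-score result."""


@dataclass(frozen=True)
class CallThresholds:
    """Decision constants of the caller.

    ``z``: aneuploidy threshold (positive strictly beyond +/-z).
    ``ff_qc``: minimum fetal fraction (inclusive) to pass QC.
    ``cnv_min_bins``: minimum reportable CNV length in bins (10 x 100 kb = 1 Mb).
    ``cnv_scan``: genome-wide Stouffer threshold of the CNV window scan.
    ``whole_chrom_fraction``: CNV segments covering more than this fraction of
    a chromosome are suppressed in favour of the aneuploidy call.
    """

    z: float = 3.0
    ff_qc: float = 0.035
    cnv_min_bins: int = 10
    cnv_scan: float = 5.0
    whole_chrom_fraction: float = 0.9


class FFEstimate(NamedTuple):
    ff: float
    method: str  # {"chrY", "configured_truth"}
    sex_call: str  # {"female", "male"}


@dataclass
class ZScoreResult:
    """Standardized dosage deviations of one sample, plus FF/QC state."""

    z_chrom: np.ndarray
    z_bins: np.ndarray | None
    proportions: np.ndarray
    total: int
    ff_estimate: float
    ff_method: str
    sex_call: str
    qc_status: Literal["pass", "redraw"]


@dataclass(frozen=True)
class CallItem:
    """One positive finding: a category plus its locus, if any."""

    category: str  # T21/T18/T13/XO/XXX/XXY/XYY/RAA/CNV
    chrom: str | None = None
    kind: str | None = None  # trisomy/monosomy for RAA, dup/del for CNV
    segment: tuple[int, int] | None = None  # CNV only, 0-based half-open

    def to_string(self) -> str:
        if self.category == "RAA":
            return f"RAA:{self.chrom}:{self.kind}"
        if self.category == "CNV":
            s, e = self.segment
            return f"CNV:{self.chrom}:{s}-{e}:{self.kind}"
        return self.category

    @classmethod
    def from_string(cls, code: str) -> "CallItem":
        parts = code.split(":")
        if parts[0] == "RAA":
            return cls("RAA", chrom=parts[1], kind=parts[2])
        if parts[0] == "CNV":
            start, _, end = parts[2].partition("-")
            return cls(
                "CNV", chrom=parts[1], kind=parts[3], segment=(int(start), int(end))
            )
        chrom = {"XO": "chrX", "XXX": "chrX", "XXY": "chrX", "XYY": "chrY",
                 "T21": "chr21", "T18": "chr18", "T13": "chr13"}.get(parts[0])
        return cls(parts[0], chrom=chrom)


@dataclass
class NIPTCall:
    """Screen result for one sample; multiple simultaneous findings allowed."""

    result: Literal["negative", "positive", "no_call"]
    calls: tuple[CallItem, ...] = ()
    evidence: dict = field(default_factory=dict)

    @property
    def categories(self) -> tuple[str, ...]:
        return tuple(c.category for c in self.calls)


@dataclass(frozen=True)
class CNVCall:
    chrom: str
    start: int
    end: int
    direction: Literal["dup", "del"]
    mean_z: float
    n_bins: int


# ---------------------------------------------------------------------------
# z-scores
# ---------------------------------------------------------------------------


def compute_z(profile: CountProfile, panel: ReferencePanel) -> tuple[np.ndarray, np.ndarray | None]:
    """Per-chromosome (and per-bin, when available) z-scores against a panel."""
    profile.validate(panel.cmap)
    if (panel.chrom_sd <= 0).any():
        raise PanelDegeneracyError("panel has non-positive chromosome SD")
    z_chrom = (profile.chrom_proportions - panel.chrom_mean) / panel.chrom_sd
    z_bins = None
    if profile.bin_counts is not None and panel.has_bins:
        z_bins = (profile.bin_proportions - panel.bin_mean) / panel.bin_sd
    return z_chrom, z_bins


def compute_z_matrix(counts: np.ndarray, total: int, panel: ReferencePanel) -> np.ndarray:
    """Vectorized chromosome-level z for a (n_samples, n_chroms) count matrix."""
    props = np.asarray(counts, dtype=float) / total
    return (props - panel.chrom_mean) / panel.chrom_sd


# ---------------------------------------------------------------------------
# Fetal fraction and QC
# ---------------------------------------------------------------------------


def _ff_from_chry(
    p_y: float, baseline: GenomeBaseline, n_y: float = 1.0
) -> float:
    """Invert the dosage mixture for FF from the chrY proportion.

    Assumes a fetus with ``n_y`` Y chromosomes and a single X (the normal
    male karyotype when ``n_y`` is 1). Clamped to [0, 1).
    """
    f = baseline.chrom_female
    f_y = f[baseline.y_index]
    f_x = f[baseline.x_index]
    yw = baseline.chry_single_copy_weight
    k = -0.5 * f_x + n_y * yw  # normalization shift of a (single-X, n_y-Y) fetus
    denom = n_y * yw - p_y * k
    if denom <= 0:
        return 0.999
    ff = (p_y - f_y) / denom
    return float(min(max(ff, 0.0), 0.999))


def estimate_ff(
    profile: CountProfile,
    female_panel: ReferencePanel,
    baseline: GenomeBaseline,
    true_ff: float | None = None,
) -> FFEstimate:
    """Fetal fraction estimate and fetal sex call.

    If the chrY proportion exceeds the female-stratum background by more than
    3 panel SDs the fetus is called male and FF is inverted from the chrY
    dosage. Otherwise the fetus is called female; genome-wide regression for
    female-fetus FF is out of scope, so in simulation mode the configured
    truth is passed through (``configured_truth``) and without it the estimate
    is NaN (treated as unassessable by QC).
    """
    yi = baseline.y_index
    p_y = float(profile.chrom_counts[yi] / profile.total)
    bg_mean = float(female_panel.chrom_mean[yi])
    bg_sd = float(female_panel.chrom_sd[yi])
    if p_y > bg_mean + 3.0 * bg_sd:
        return FFEstimate(_ff_from_chry(p_y, baseline), "chrY", "male")
    ff = float("nan") if true_ff is None else float(true_ff)
    return FFEstimate(ff, "configured_truth", "female")


def qc_check(ff_estimate: float, threshold: float = 0.035) -> str:
    """QC on fetal fraction: pass iff FF >= threshold (inclusive).

    A NaN estimate (female fetus without a configured truth) passes, since no
    FF evidence exists to fail it on.
    """
    if np.isnan(ff_estimate):
        return "pass"
    return "pass" if ff_estimate >= threshold else "redraw"


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------


def _male_sex_chrom_call(
    zres: ZScoreResult, baseline: GenomeBaseline, z_threshold: float
) -> tuple[CallItem | None, dict]:
    """XXY/XYY resolution by joint (chrX, chrY) dosage-model scoring."""
    p = zres.proportions
    xi, yi = baseline.x_index, baseline.y_index
    p_x, p_y = float(p[xi]), float(p[yi])
    f = baseline.chrom_female
    yw = baseline.chry_single_copy_weight

    # candidate karyotypes: (X copy ratio vs maternal, Y copies)
    candidates = {"XY": (0.5, 1.0), "XXY": (1.0, 1.0), "XYY": (0.5, 2.0)}
    zx: dict[str, float] = {}
    f_y = f[yi]
    var_py = p_y * (1.0 - p_y) / zres.total
    for name, (r_x, n_y) in candidates.items():
        k = (r_x - 1.0) * f[xi] + n_y * yw

        def ff_of(py: float) -> float:
            denom = n_y * yw - py * k
            if denom <= 0:
                return 0.999
            return min(max((py - f_y) / denom, 0.0), 0.999)

        def px_of(ff: float) -> float:
            return f[xi] * (1.0 - ff + ff * r_x) / (1.0 + ff * k)

        ff_k = ff_of(p_y)
        p_x_exp = px_of(ff_k)
        # propagate chrY counting noise through the implied FF into the
        # expected chrX proportion, so z_X is ~N(0,1) under the candidate
        d_ff = (ff_of(p_y + 1e-6) - ff_of(p_y - 1e-6)) / 2e-6
        d_px = (px_of(min(ff_k + 1e-6, 0.999)) - px_of(max(ff_k - 1e-6, 0.0))) / 2e-6
        var_x = p_x_exp * (1.0 - p_x_exp) / zres.total + (d_px * d_ff) ** 2 * var_py
        zx[name] = (p_x - p_x_exp) / np.sqrt(var_x)

    evidence = {f"z_X|{k}": v for k, v in zx.items()}
    if abs(zx["XY"]) <= z_threshold:
        return None, evidence
    best = min(("XXY", "XYY"), key=lambda k: abs(zx[k]))
    return CallItem(category=best, chrom="chrX" if best == "XXY" else "chrY"), evidence


def classify(
    zres: ZScoreResult,
    baseline: GenomeBaseline,
    thresholds: CallThresholds = CallThresholds(),
    cnv_calls: Sequence[CNVCall] | None = None,
) -> NIPTCall:
    """Map z-scores (and optional CNV segments) to a screen call.

    Autosome N is positive iff |z_N| > threshold: chr21/18/13 excess gives the
    common trisomies, other autosomal deviations give RAA calls. Sex
    chromosomes follow the documented dosage rules. Boundary ties (|z| exactly
    at the threshold) are negative.
    """
    if zres.qc_status != "pass":
        raise QCStateError("cannot classify a QC-failed sample")
    cmap = baseline.cmap
    zt = thresholds.z
    calls: list[CallItem] = []
    evidence: dict = {}

    aneuploid_chroms: set[str] = set()
    for chrom in AUTOSOMES:
        z = float(zres.z_chrom[cmap.chrom_index[chrom]])
        if abs(z) <= zt:
            continue
        evidence[chrom] = z
        aneuploid_chroms.add(chrom)
        if z > zt and chrom == "chr21":
            calls.append(CallItem("T21", chrom="chr21"))
        elif z > zt and chrom == "chr18":
            calls.append(CallItem("T18", chrom="chr18"))
        elif z > zt and chrom == "chr13":
            calls.append(CallItem("T13", chrom="chr13"))
        else:
            kind = "trisomy" if z > zt else "monosomy"
            calls.append(CallItem("RAA", chrom=chrom, kind=kind))

    xi = baseline.x_index
    if zres.sex_call == "female":
        z_x = float(zres.z_chrom[xi])
        evidence["chrX"] = z_x
        if z_x < -zt:
            calls.append(CallItem("XO", chrom="chrX"))
        elif z_x > zt:
            calls.append(CallItem("XXX", chrom="chrX"))
    else:
        item, sex_evidence = _male_sex_chrom_call(zres, baseline, zt)
        evidence.update(sex_evidence)
        if item is not None:
            calls.append(item)

    if cnv_calls:
        for c in cnv_calls:
            if c.chrom in aneuploid_chroms:
                continue  # dosage already explained by the whole-chromosome call
            calls.append(
                CallItem("CNV", chrom=c.chrom, kind=c.direction, segment=(c.start, c.end))
            )
            evidence[f"{c.chrom}:{c.start}-{c.end}"] = c.mean_z

    result = "positive" if calls else "negative"
    return NIPTCall(result=result, calls=tuple(calls), evidence=evidence)


# ---------------------------------------------------------------------------
# CNV scan
# ---------------------------------------------------------------------------


def call_cnv(
    z_bins: np.ndarray,
    cmap: ChromosomeMap,
    min_consecutive_bins: int = 10,
    z_threshold: float = 3.0,
    scan_threshold: float = 5.0,
    whole_chrom_fraction: float = 0.9,
) -> list[CNVCall]:
    """Windowed scan for sub-chromosomal dosage segments on bin z-scores.

    Per-bin z values are winsorised at ``+/- z_threshold`` (a lone outlier bin
    can then never drive a call) and combined over sliding windows at
    geometrically growing scales starting at ``min_consecutive_bins``; a
    window is a candidate when its Stouffer statistic ``sum(z)/sqrt(w)``
    exceeds ``scan_threshold``, chosen to keep the expected number of false
    windows per euploid genome well below one. Same-sign overlapping windows
    are merged and boundaries refined to the maximum-sum subarray. Segments
    covering nearly the whole chromosome are suppressed (the aneuploidy call
    reports those).
    """
    if min_consecutive_bins < 1:
        raise ValueError("min_consecutive_bins must be >= 1")
    z = np.clip(np.asarray(z_bins, dtype=float), -z_threshold, z_threshold)
    out: list[CNVCall] = []

    for ci, chrom in enumerate(cmap.names):
        sl = cmap.bin_slice(chrom)
        zc = z[sl]
        n = len(zc)
        if n < min_consecutive_bins:
            continue
        csum = np.concatenate([[0.0], np.cumsum(zc)])

        hits: list[tuple[int, int, int]] = []  # (start, end, sign)
        w = min_consecutive_bins
        while w <= n:
            stride = max(1, w // 2)
            starts = np.arange(0, n - w + 1, stride)
            s = (csum[starts + w] - csum[starts]) / np.sqrt(w)
            for st, val in zip(starts, s):
                if abs(val) > scan_threshold:
                    hits.append((int(st), int(st + w), 1 if val > 0 else -1))
            if w == n:
                break
            w = min(2 * w, n)
        if not hits:
            continue

        # merge overlapping same-sign windows
        hits.sort()
        merged: list[list[int]] = []
        for st, en, sign in hits:
            if merged and sign == merged[-1][2] and st <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], en)
            else:
                merged.append([st, en, sign])

        for st, en, sign in merged:
            seg = zc[st:en] * sign
            # boundary refinement: maximum-sum subarray with a per-bin
            # extension penalty at half the estimated dosage effect, so that
            # noise drift outside the true segment cannot stretch the call
            b, e = 0, len(seg)
            for _ in range(2):
                effect = max(float(seg[b:e].mean()), 0.1)
                b2, e2 = _max_subarray(seg - 0.5 * effect)
                if (b2, e2) == (b, e):
                    break
                b, e = b2, e2
            b, e = st + b, st + e
            width = e - b
            if width < min_consecutive_bins:
                continue
            stouffer = (csum[e] - csum[b]) / np.sqrt(width) * sign
            if stouffer <= scan_threshold:
                continue
            if width > whole_chrom_fraction * n:
                continue
            raw = np.asarray(z_bins, dtype=float)[sl][b:e]
            out.append(
                CNVCall(
                    chrom=chrom,
                    start=int(cmap.bin_starts[sl][b]),
                    end=int(cmap.bin_ends[sl][e - 1]),
                    direction="dup" if sign > 0 else "del",
                    mean_z=float(raw.mean()),
                    n_bins=int(width),
                )
            )
    return out


def _max_subarray(x: np.ndarray) -> tuple[int, int]:
    """Kadane: indices [b, e) of the maximum-sum contiguous subarray."""
    best, best_b, best_e = -np.inf, 0, 1
    cur, cur_b = 0.0, 0
    for i, v in enumerate(x):
        if cur <= 0:
            cur, cur_b = v, i
        else:
            cur += v
        if cur > best:
            best, best_b, best_e = cur, cur_b, i + 1
    return best_b, best_e


# ---------------------------------------------------------------------------
# One-sample screen
# ---------------------------------------------------------------------------


def screen_sample(
    profile: CountProfile,
    panels: dict[str, ReferencePanel],
    baseline: GenomeBaseline,
    thresholds: CallThresholds = CallThresholds(),
    true_ff: float | None = None,
) -> tuple[ZScoreResult, NIPTCall | None]:
    """FF estimation, QC, z-scores against the called-sex stratum, and the call.

    Returns the z-score result and the call; the call is ``None`` when QC
    demands a redraw (the pipeline owns the redraw budget).
    """
    ffest = estimate_ff(profile, panels["female"], baseline, true_ff=true_ff)
    qc = qc_check(ffest.ff, thresholds.ff_qc)
    stratum = "male" if ffest.sex_call == "male" else "female"
    z_chrom, z_bins = compute_z(profile, panels[stratum])
    zres = ZScoreResult(
        z_chrom=z_chrom,
        z_bins=z_bins,
        proportions=profile.chrom_proportions,
        total=profile.total,
        ff_estimate=ffest.ff,
        ff_method=ffest.method,
        sex_call=ffest.sex_call,
        qc_status=qc,
    )
    if qc != "pass":
        return zres, None
    cnvs = None
    if z_bins is not None:
        cnvs = call_cnv(
            z_bins,
            baseline.cmap,
            min_consecutive_bins=thresholds.cnv_min_bins,
            z_threshold=thresholds.z,
            scan_threshold=thresholds.cnv_scan,
            whole_chrom_fraction=thresholds.whole_chrom_fraction,
        )
    call = classify(zres, baseline, thresholds, cnv_calls=cnvs)
    return zres, call
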