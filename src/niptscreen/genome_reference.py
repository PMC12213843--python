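"""Genomic coordinate model and euploid reference panels.

cfDNA screening for fetal aneuploidy compares, for every chromosome N, the
fraction of a sample's uniquely mapped reads assigned to N against the same
fraction in a panel of euploid reference pregnancies:

    z_N = (%chrN_test - mean(%chrN_ref)) / sd(%chrN_ref)

This module owns the coordinate system those fractions live on (a fixed
chromosome table tiled by uniform bins) and the reference panel itself
(per-chromosome and per-bin mean/SD of read proportions), including a
plain-text TSV serialization.

Chromosome lengths are the GRCh37 assembly table shipped as a constant; every
statistic downstream is proportion-based, so the exact build only fixes the
relative bin layout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import cached_property
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GRCH37_LENGTHS",
    "ChromosomeMap",
    "CountProfile",
    "ReferencePanel",
    "PanelDegeneracyError",
    "InvalidProfileError",
    "PanelFormatError",
    "build_reference_panel",
    "save_panel",
    "load_panel",
]

#: GRCh37 chromosome lengths in base pairs, chr1..chr22, chrX, chrY.
GRCH37_LENGTHS: dict[str, int] = {
    "chr1": 249_250_621,
    "chr2": 243_199_373,
    "chr3": 198_022_430,
    "chr4": 191_154_276,
    "chr5": 180_915_260,
    "chr6": 171_115_067,
    "chr7": 159_138_663,
    "chr8": 146_364_022,
    "chr9": 141_213_431,
    "chr10": 135_534_747,
    "chr11": 135_006_516,
    "chr12": 133_851_895,
    "chr13": 115_169_878,
    "chr14": 107_349_540,
    "chr15": 102_531_392,
    "chr16": 90_354_753,
    "chr17": 81_195_210,
    "chr18": 78_077_248,
    "chr19": 59_128_983,
    "chr20": 63_025_520,
    "chr21": 48_129_895,
    "chr22": 51_304_566,
    "chrX": 155_270_560,
    "chrY": 59_373_566,
}

AUTOSOMES: tuple[str, ...] = tuple(f"chr{i}" for i in range(1, 23))


class PanelDegeneracyError(ValueError):
    """Reference panel cannot support a z-score (too few samples or zero SD)."""


class InvalidProfileError(ValueError):
    """A count profile violates its invariants (e.g. zero total)."""


class PanelFormatError(ValueError):
    """A serialized panel file does not parse against the expected schema."""


@dataclass(frozen=True)
class ChromosomeMap:
    """Ordered chromosomes with lengths, tiled by uniform half-open bins.

    Bins are 0-based half-open ``[start, end)``; the last bin of each
    chromosome is clipped to the chromosome length so bins tile exactly.
    """

    names: tuple[str, ...]
    lengths: tuple[int, ...]
    bin_size: int

    def __post_init__(self) -> None:
        if len(self.names) != len(self.lengths):
            raise ValueError("names and lengths differ in length")
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate chromosome names")
        if any(l <= 0 for l in self.lengths):
            raise ValueError("all chromosome lengths must be > 0")
        if self.bin_size <= 0:
            raise ValueError("bin_size must be > 0")

    @classmethod
    def grch37(cls, bin_size: int = 100_000) -> "ChromosomeMap":
        return cls(
            names=tuple(GRCH37_LENGTHS),
            lengths=tuple(GRCH37_LENGTHS.values()),
            bin_size=bin_size,
        )

    @property
    def n_chroms(self) -> int:
        return len(self.names)

    @cached_property
    def chrom_index(self) -> dict[str, int]:
        return {name: i for i, name in enumerate(self.names)}

    @cached_property
    def bins_per_chrom(self) -> np.ndarray:
        return np.array(
            [math.ceil(l / self.bin_size) for l in self.lengths], dtype=np.int64
        )

    @property
    def total_bins(self) -> int:
        return int(self.bins_per_chrom.sum())

    @cached_property
    def bin_offsets(self) -> np.ndarray:
        """Start index of each chromosome's bin block in the flat bin vector."""
        return np.concatenate([[0], np.cumsum(self.bins_per_chrom)])

    def bin_slice(self, chrom: str) -> slice:
        i = self.chrom_index[chrom]
        return slice(int(self.bin_offsets[i]), int(self.bin_offsets[i + 1]))

    @cached_property
    def bin_starts(self) -> np.ndarray:
        starts = []
        for n in self.bins_per_chrom:
            starts.append(np.arange(n, dtype=np.int64) * self.bin_size)
        return np.concatenate(starts)

    @cached_property
    def bin_ends(self) -> np.ndarray:
        ends = []
        for length, n in zip(self.lengths, self.bins_per_chrom):
            e = (np.arange(n, dtype=np.int64) + 1) * self.bin_size
            e[-1] = length
            ends.append(e)
        return np.concatenate(ends)

    @cached_property
    def bin_widths(self) -> np.ndarray:
        return self.bin_ends - self.bin_starts

    @cached_property
    def bin_chroms(self) -> np.ndarray:
        """Chromosome index of every bin in the flat bin vector."""
        return np.repeat(np.arange(self.n_chroms), self.bins_per_chrom)

    def bin_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": np.asarray(self.names)[self.bin_chroms],
                "start": self.bin_starts,
                "end": self.bin_ends,
            }
        )


@dataclass
class CountProfile:
    """Unique-read counts for one sample.

    ``chrom_counts`` always has one entry per chromosome of the map;
    ``bin_counts`` is optional (bin-resolution simulation/calling only).
    """

    chrom_counts: np.ndarray
    total: int
    bin_counts: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.chrom_counts = np.asarray(self.chrom_counts, dtype=np.int64)
        if self.bin_counts is not None:
            self.bin_counts = np.asarray(self.bin_counts, dtype=np.int64)

    def validate(self, cmap: ChromosomeMap) -> None:
        if self.chrom_counts.shape != (cmap.n_chroms,):
            raise InvalidProfileError(
                f"chrom_counts has shape {self.chrom_counts.shape}, "
                f"expected ({cmap.n_chroms},)"
            )
        if (self.chrom_counts < 0).any():
            raise InvalidProfileError("negative chromosome count")
        if self.total <= 0:
            raise InvalidProfileError("total unique count must be > 0")
        if int(self.chrom_counts.sum()) != self.total:
            raise InvalidProfileError("chromosome counts do not sum to total")
        if self.bin_counts is not None:
            if self.bin_counts.shape != (cmap.total_bins,):
                raise InvalidProfileError("bin_counts length does not match map")
            per_chrom = np.bincount(
                cmap.bin_chroms, weights=self.bin_counts, minlength=cmap.n_chroms
            ).astype(np.int64)
            if not np.array_equal(per_chrom, self.chrom_counts):
                raise InvalidProfileError("bin counts do not sum to chromosome counts")

    @property
    def chrom_proportions(self) -> np.ndarray:
        return self.chrom_counts / self.total

    @property
    def bin_proportions(self) -> np.ndarray | None:
        if self.bin_counts is None:
            return None
        return self.bin_counts / self.total


@dataclass
class ReferencePanel:
    """Per-chromosome (and optionally per-bin) moments of euploid read proportions.

    ``sex_stratum`` records which reference population the panel describes:
    chrX/chrY proportions differ systematically between pregnancies carrying
    female and male fetuses, so sex-chromosome z-scores are only well defined
    against the matching stratum.
    """

    cmap: ChromosomeMap
    n_ref: int
    sex_stratum: str  # {"female_fetus", "male_fetus", "pooled"}
    chrom_mean: np.ndarray
    chrom_sd: np.ndarray
    bin_mean: np.ndarray | None = None
    bin_sd: np.ndarray | None = None

    _STRATA = ("female_fetus", "male_fetus", "pooled")

    def __post_init__(self) -> None:
        if self.sex_stratum not in self._STRATA:
            raise ValueError(f"sex_stratum must be one of {self._STRATA}")
        if self.n_ref < 2:
            raise PanelDegeneracyError("reference panel needs at least 2 samples")
        self.chrom_mean = np.asarray(self.chrom_mean, dtype=float)
        self.chrom_sd = np.asarray(self.chrom_sd, dtype=float)
        if abs(self.chrom_mean.sum() - 1.0) > 1e-9:
            raise ValueError("chrom_mean must sum to 1 within 1e-9")
        if (self.chrom_sd <= 0).any():
            raise PanelDegeneracyError("all panel SD entries must be > 0")

    @property
    def has_bins(self) -> bool:
        return self.bin_mean is not None and self.bin_sd is not None

    def mean_of(self, chrom: str) -> float:
        return float(self.chrom_mean[self.cmap.chrom_index[chrom]])

    def sd_of(self, chrom: str) -> float:
        return float(self.chrom_sd[self.cmap.chrom_index[chrom]])


def build_reference_panel(
    profiles: Sequence[CountProfile] | Iterable[CountProfile],
    cmap: ChromosomeMap,
    sex_stratum: str = "pooled",
) -> ReferencePanel:
    """Estimate panel moments from euploid reference samples.

    Means and SDs are the sample mean and sample SD (n-1 denominator) of the
    per-sample read proportions, at chromosome resolution always and at bin
    resolution when every profile carries bin counts.
    """
    profiles = list(profiles)
    if len(profiles) < 2:
        raise PanelDegeneracyError(
            f"need at least 2 reference profiles, got {len(profiles)}"
        )
    for p in profiles:
        p.validate(cmap)

    props = np.stack([p.chrom_proportions for p in profiles])
    chrom_mean = props.mean(axis=0)
    chrom_sd = props.std(axis=0, ddof=1)
    if (chrom_sd <= 0).any():
        bad = [cmap.names[i] for i in np.flatnonzero(chrom_sd <= 0)]
        raise PanelDegeneracyError(
            f"zero reference SD on {', '.join(bad)}: panel cannot standardize"
        )
    # renormalize away accumulated float error so the panel invariant holds
    chrom_mean = chrom_mean / chrom_mean.sum()

    bin_mean = bin_sd = None
    if all(p.bin_counts is not None for p in profiles):
        bprops = np.stack([p.bin_proportions for p in profiles])
        bin_mean = bprops.mean(axis=0)
        bin_sd = bprops.std(axis=0, ddof=1)
        if (bin_sd <= 0).any():
            raise PanelDegeneracyError("zero reference SD in at least one bin")

    return ReferencePanel(
        cmap=cmap,
        n_ref=len(profiles),
        sex_stratum=sex_stratum,
        chrom_mean=chrom_mean,
        chrom_sd=chrom_sd,
        bin_mean=bin_mean,
        bin_sd=bin_sd,
    )


_PANEL_COLUMNS = ["level", "chrom", "start", "end", "mean", "sd"]


def save_panel(panel: ReferencePanel, destination: str | Path) -> None:
    """Write a panel as TSV: header comments, then one row per chromosome and bin.

    Floats use repr-precision (%.17g) so that load(save(panel)) is bit-exact.
    """
    destination = Path(destination)
    cmap = panel.cmap
    lines = [
        "# niptscreen reference panel",
        f"# n_ref={panel.n_ref}",
        f"# sex_stratum={panel.sex_stratum}",
        f"# bin_size={cmap.bin_size}",
        "\t".join(_PANEL_COLUMNS),
    ]
    for i, name in enumerate(cmap.names):
        lines.append(
            f"chrom\t{name}\t0\t{cmap.lengths[i]}"
            f"\t{panel.chrom_mean[i]:.17g}\t{panel.chrom_sd[i]:.17g}"
        )
    if panel.has_bins:
        chrom_names = np.asarray(cmap.names)[cmap.bin_chroms]
        for name, s, e, m, sd in zip(
            chrom_names, cmap.bin_starts, cmap.bin_ends, panel.bin_mean, panel.bin_sd
        ):
            lines.append(f"bin\t{name}\t{s}\t{e}\t{m:.17g}\t{sd:.17g}")
    destination.write_text("\n".join(lines) + "\n")


def load_panel(source: str | Path) -> ReferencePanel:
    """Parse a TSV panel written by :func:`save_panel`."""
    source = Path(source)
    meta: dict[str, str] = {}
    header: list[str] | None = None
    chrom_rows: list[tuple[str, int, float, float]] = []
    bin_rows: list[tuple[str, int, int, float, float]] = []

    for lineno, raw in enumerate(source.read_text().splitlines(), start=1):
        if not raw.strip():
            continue
        if raw.startswith("#"):
            body = raw.lstrip("#").strip()
            if "=" in body:
                key, _, value = body.partition("=")
                meta[key.strip()] = value.strip()
            continue
        parts = raw.split("\t")
        if header is None:
            header = parts
            missing = [c for c in _PANEL_COLUMNS if c not in header]
            if missing:
                raise PanelFormatError(
                    f"{source}: header missing column(s) {', '.join(missing)}"
                )
            continue
        row = dict(zip(header, parts))
        try:
            level = row["level"]
            chrom = row["chrom"]
            start = int(row["start"])
            end = int(row["end"])
            mean = float(row["mean"])
            sd = float(row["sd"])
        except (KeyError, ValueError) as exc:
            raise PanelFormatError(f"{source}:{lineno}: bad row ({exc})") from exc
        if level == "chrom":
            chrom_rows.append((chrom, end, mean, sd))
        elif level == "bin":
            bin_rows.append((chrom, start, end, mean, sd))
        else:
            raise PanelFormatError(f"{source}:{lineno}: unknown level {level!r}")

    if header is None or not chrom_rows:
        raise PanelFormatError(f"{source}: no chromosome rows found")
    for key in ("n_ref", "sex_stratum", "bin_size"):
        if key not in meta:
            raise PanelFormatError(f"{source}: missing metadata field {key}")

    cmap = ChromosomeMap(
        names=tuple(r[0] for r in chrom_rows),
        lengths=tuple(r[1] for r in chrom_rows),
        bin_size=int(meta["bin_size"]),
    )
    chrom_mean = np.array([r[2] for r in chrom_rows])
    chrom_sd = np.array([r[3] for r in chrom_rows])

    bin_mean = bin_sd = None
    if bin_rows:
        if len(bin_rows) != cmap.total_bins:
            raise PanelFormatError(
                f"{source}: {len(bin_rows)} bin rows, expected {cmap.total_bins}"
            )
        bin_mean = np.array([r[3] for r in bin_rows])
        bin_sd = np.array([r[4] for r in bin_rows])

    return ReferencePanel(
        cmap=cmap,
        n_ref=int(meta["n_ref"]),
        sex_stratum=meta["sex_stratum"],
        chrom_mean=chrom_mean,
        chrom_sd=chrom_sd,
        bin_mean=bin_mean,
        bin_sd=bin_sd,
    )
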