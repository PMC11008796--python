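"""Genetic maps and recombination fractions.

A :class:`LinkageMap` places biallelic loci on chromosomes with sex-specific
genetic positions.  Two conventions are supported for turning map distance
into recombination fractions:

``"interval"``
    The toy-genome convention: the genetic distance between *adjacent* loci
    (in Morgans) is read directly as their recombination fraction, and the
    fraction between non-adjacent loci follows from independent per-interval
    crossovers (no interference),

    .. math:: c(l_1, l_2) = \\tfrac{1}{2}\\bigl(1 - \\prod_i (1 - 2 c_i)\\bigr),

    the product running over the intervening intervals.  This matches the
    meiosis model of the simulator exactly.

``"kosambi"``
    The empirical-map convention: the fraction between two loci on the same
    chromosome is Kosambi's map function applied separately to the female
    and male genetic distances, then averaged.  Loci on different
    chromosomes always have c = 1/2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "LinkageMap",
    "kosambi_c",
    "uniform_map",
    "apportion_loci",
    "read_genetic_map",
    "synthetic_autosome_table",
]


def kosambi_c(d):
    """Recombination fraction for genetic distance ``d`` (Morgans), Kosambi.

    c(d) = tanh(2d) / 2; strictly increasing, c(0) = 0, c(inf) = 1/2.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("genetic distance must be non-negative")
    out = 0.5 * np.tanh(2.0 * d)
    return out if out.ndim else float(out)


@dataclass
class LinkageMap:
    """Ordered loci with chromosome labels and sex-specific genetic positions.

    Positions are cumulative centimorgans within each chromosome; physical
    positions are 1-based base pairs.  Loci must be sorted by
    (chromosome, bp) with non-decreasing genetic positions per chromosome.
    """

    chrom: np.ndarray
    bp: np.ndarray
    cm_female: np.ndarray
    cm_male: np.ndarray
    convention: str = "kosambi"  # "kosambi" or "interval"

    _switch_cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        self.chrom = np.asarray(self.chrom, dtype=np.int64)
        self.bp = np.asarray(self.bp, dtype=np.int64)
        self.cm_female = np.asarray(self.cm_female, dtype=float)
        self.cm_male = np.asarray(self.cm_male, dtype=float)
        n = self.chrom.size
        if not (self.bp.size == self.cm_female.size == self.cm_male.size == n):
            raise ValueError("field lengths differ")
        if self.convention not in ("kosambi", "interval"):
            raise ValueError(f"unknown convention {self.convention!r}")
        order = np.lexsort((self.bp, self.chrom))
        if not np.array_equal(order, np.arange(n)):
            raise ValueError("loci must be sorted by (chromosome, bp)")
        for cm in (self.cm_female, self.cm_male):
            same = self.chrom[1:] == self.chrom[:-1]
            if np.any(np.diff(cm)[same] < -1e-12):
                raise ValueError("genetic positions must be non-decreasing within chromosomes")

    @property
    def n_loci(self) -> int:
        return int(self.chrom.size)

    # -- meiosis support ---------------------------------------------------

    def interval_switch_probs(self, sex: str) -> np.ndarray:
        """Per-locus haplotype switch probabilities for gamete formation.

        Entry 0 and every chromosome-start entry are 1/2 (independent fair
        starting haplotype per chromosome); within-chromosome entries are the
        adjacent-interval recombination fractions on the requested map
        (``"female"`` or ``"male"``).
        """
        key = sex
        if key in self._switch_cache:
            return self._switch_cache[key]
        cm = {"female": self.cm_female, "male": self.cm_male}[sex]
        new_chrom = np.empty(self.n_loci, dtype=bool)
        new_chrom[0] = True
        new_chrom[1:] = self.chrom[1:] != self.chrom[:-1]
        d = np.empty(self.n_loci)
        d[0] = 0.0
        d[1:] = np.diff(cm) / 100.0  # Morgans
        d[new_chrom] = 0.0  # boundary entries are replaced by fair starts below
        if self.convention == "interval":
            c = np.minimum(d, 0.5)
        else:
            c = kosambi_c(d)
        c = np.asarray(c, dtype=float)
        c[new_chrom] = 0.5
        self._switch_cache[key] = c
        return c

    # -- pairwise fractions ------------------------------------------------

    def pairwise_c(self, l1: int, l2: int) -> float:
        """Sex-averaged recombination fraction between two loci."""
        n = self.n_loci
        if not (0 <= l1 < n and 0 <= l2 < n):
            raise IndexError("locus index out of range")
        if l1 == l2:
            return 0.0
        if self.chrom[l1] != self.chrom[l2]:
            return 0.5
        i, j = sorted((l1, l2))
        if self.convention == "interval":
            cf = self.interval_switch_probs("female")[i + 1 : j + 1]
            cm = self.interval_switch_probs("male")[i + 1 : j + 1]
            c_f = 0.5 * (1.0 - np.prod(1.0 - 2.0 * cf))
            c_m = 0.5 * (1.0 - np.prod(1.0 - 2.0 * cm))
        else:
            c_f = kosambi_c(abs(self.cm_female[j] - self.cm_female[i]) / 100.0)
            c_m = kosambi_c(abs(self.cm_male[j] - self.cm_male[i]) / 100.0)
        return float(0.5 * (c_f + c_m))

    def pairwise_c_matrix(self, loci=None) -> np.ndarray:
        """Matrix of sex-averaged pairwise recombination fractions."""
        idx = np.arange(self.n_loci) if loci is None else np.asarray(loci)
        k = idx.size
        if self.convention == "kosambi":
            df = np.abs(self.cm_female[idx][:, None] - self.cm_female[idx][None, :]) / 100.0
            dm = np.abs(self.cm_male[idx][:, None] - self.cm_male[idx][None, :]) / 100.0
            c = 0.5 * (kosambi_c(df) + kosambi_c(dm))
        else:
            # cumulative log(1-2c_i) per sex gives all pair products at once
            new_chrom = np.empty(self.n_loci, dtype=bool)
            new_chrom[0] = True
            new_chrom[1:] = self.chrom[1:] != self.chrom[:-1]
            out = np.zeros((k, k))
            for sex in ("female", "male"):
                ci = self.interval_switch_probs(sex).astype(float)
                lg = np.zeros(self.n_loci)
                ok = ~new_chrom & (ci < 0.5)
                lg[ok] = np.log1p(-2.0 * ci[ok])
                # an interval with c = 1/2 fully decouples its flanks, like a
                # chromosome break: give those pairs a fresh segment id
                seg_all = np.cumsum(new_chrom | (ci >= 0.5))
                cs = np.concatenate([[0.0], np.cumsum(lg[1:])])[idx]
                seg = seg_all[idx]
                prod = np.exp(-np.abs(cs[:, None] - cs[None, :]))
                prod[seg[:, None] != seg[None, :]] = 0.0
                out += 0.5 * (1.0 - prod)
            c = out / 2.0
        diff_chrom = self.chrom[idx][:, None] != self.chrom[idx][None, :]
        c[diff_chrom] = 0.5
        np.fill_diagonal(c, 0.0)
        return c

    def harmonic_mean_c(self, loci=None) -> float:
        """Harmonic mean recombination fraction over distinct locus pairs.

        c_h = [|L| (|L|-1) / 2] / sum over pairs of 1/c.  Undefined (raises)
        if any pair has c = 0.
        """
        c = self.pairwise_c_matrix(loci)
        k = c.shape[0]
        if k < 2:
            raise ValueError("need at least two loci")
        iu = np.triu_indices(k, 1)
        vals = c[iu]
        if np.any(vals <= 0):
            raise ValueError("harmonic mean undefined: some pair has zero recombination")
        return float(vals.size / np.sum(1.0 / vals))


def uniform_map(n_loci: int, total_morgans: float) -> LinkageMap:
    """Single chromosome with a constant adjacent-locus recombination fraction.

    The adjacent fraction is ``total_morgans / (n_loci - 1)`` read directly as
    a fraction (interval convention), identical on the female and male maps;
    e.g. 1000 loci on a 1-Morgan chromosome give c = 1/999 between neighbours.
    """
    if n_loci < 2:
        raise ValueError("need at least two loci")
    if total_morgans < 0:
        raise ValueError("map length must be non-negative")
    cm = np.linspace(0.0, 100.0 * total_morgans, n_loci)
    bp = np.arange(1, n_loci + 1, dtype=np.int64)
    chrom = np.ones(n_loci, dtype=np.int64)
    return LinkageMap(chrom, bp, cm, cm.copy(), convention="interval")


def _largest_remainder(shares: np.ndarray, n: int) -> np.ndarray:
    base = np.floor(shares).astype(int)
    rem = shares - base
    short = n - base.sum()
    # deterministic tie-break: larger remainder first, then lower chromosome index
    order = np.lexsort((np.arange(shares.size), -rem))
    base[order[:short]] += 1
    return base


def apportion_loci(chrom_table: pd.DataFrame, n_loci: int) -> LinkageMap:
    """Spread loci over chromosomes proportionally to physical length.

    ``chrom_table`` needs columns ``chrom``, ``bp_length``, ``cm_female``,
    ``cm_male`` (per-chromosome totals).  Allotments use largest-remainder
    rounding on bp length; within each chromosome loci sit at interval
    midpoints of its sex-averaged genetic length, with female/male positions
    scaled in proportion to that chromosome's female/male map lengths.
    """
    t = chrom_table.reset_index(drop=True)
    bp_len = t["bp_length"].to_numpy(dtype=float)
    shares = n_loci * bp_len / bp_len.sum()
    counts = _largest_remainder(shares, n_loci)
    chrom, bp, cmf, cmm = [], [], [], []
    for k in range(len(t)):
        m = counts[k]
        if m == 0:
            continue
        s_avg = 0.5 * (t["cm_female"][k] + t["cm_male"][k])
        x = (np.arange(m) + 0.5) / m  # fractional positions along the chromosome
        chrom.append(np.full(m, t["chrom"][k], dtype=np.int64))
        bp.append(np.maximum(1, np.round(x * bp_len[k]).astype(np.int64)))
        cmf.append(x * s_avg * (t["cm_female"][k] / s_avg if s_avg > 0 else 0.0))
        cmm.append(x * s_avg * (t["cm_male"][k] / s_avg if s_avg > 0 else 0.0))
    return LinkageMap(
        np.concatenate(chrom),
        np.concatenate(bp),
        np.concatenate(cmf),
        np.concatenate(cmm),
        convention="kosambi",
    )


def read_genetic_map(path) -> LinkageMap:
    """Read a whitespace-delimited map with columns chr pos_bp cM_female cM_male."""
    df = pd.read_csv(path, sep=r"\s+")
    df.columns = [c.lower() for c in df.columns]
    df = df.rename(columns={"chr": "chrom", "pos_bp": "bp"})
    df = df.sort_values(["chrom", "bp"], kind="stable")
    return LinkageMap(
        df["chrom"].to_numpy(),
        df["bp"].to_numpy(),
        df["cm_female"].to_numpy(),
        df["cm_male"].to_numpy(),
        convention="kosambi",
    )


def synthetic_autosome_table() -> pd.DataFrame:
    """Approximate 22-autosome lengths (synthetic stand-in for a real map).

    Physical lengths follow the GRCh38 assembly (Mb, rounded); the female and
    male genetic lengths are synthetic linear approximations to published
    pedigree maps (female ~ 1.50 cM/Mb + 37 cM, male ~ 0.88 cM/Mb + 15 cM),
    adequate for multi-chromosome simulation experiments but not a substitute
    for a measured map.
    """
    mb = np.array([
        248.96, 242.19, 198.30, 190.21, 181.54, 170.81, 159.35, 145.14,
        138.39, 133.80, 135.09, 133.28, 114.36, 107.04, 101.99, 90.34,
        83.26, 80.37, 58.62, 64.44, 46.71, 50.82,
    ])
    return pd.DataFrame({
        "chrom": np.arange(1, 23),
        "bp_length": (mb * 1e6).astype(np.int64),
        "cm_female": 1.50 * mb + 37.0,
        "cm_male": 0.88 * mb + 15.0,
    })
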