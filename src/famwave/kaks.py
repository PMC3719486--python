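"""Pairwise Ka/Ks by Nei-Gojobori (1986) pathway counting.

Synonymous and nonsynonymous *sites* are counted per codon as the expected
fraction of single-base changes that are synonymous, excluding changes that
would create a stop codon from the denominator.  *Differences* between two
codons are averaged over all orderings of the minimal mutation path;
orderings that pass through a stop codon are excluded (if every ordering is
blocked, the average falls back to all orderings).  Proportions are
corrected for multiple hits with the Jukes-Cantor formula
``d = -(3/4) ln(1 - (4/3) p)``; ``p >= 3/4`` is flagged saturated.

Sliding windows (default 150 bp window, 9 bp step) profile the ratio along
a pairwise codon alignment; group contrasts use the Kruskal-Wallis rank
test.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations

import numpy as np
from scipy import stats

from .synthetic import GENETIC_CODE, STOP_CODONS

__all__ = [
    "KaKsResult",
    "KaKsProfile",
    "Window",
    "ng86_codon_sites",
    "ng86_pair_diffs",
    "kaks_pair",
    "sliding_window",
    "region_kaks",
    "kruskal_wallis",
]

logger = logging.getLogger(__name__)

_BASES = "TCAG"
_VALID = set(_BASES)
_GAPPY = set("-.")


def _check_codon(codon: str) -> str:
    codon = codon.upper()
    if len(codon) != 3 or set(codon) - _VALID:
        raise ValueError(f"ambiguous or malformed codon {codon!r}")
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon!r}")
    return codon


@lru_cache(maxsize=None)
def ng86_codon_sites(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts for one codon.

    Per position the synonymous fraction is (# synonymous changes) /
    (# changes not creating a stop); nonsynonymous sites are 3 - s.
    """
    codon = _check_codon(codon)
    aa = GENETIC_CODE[codon]
    s = 0.0
    for pos in range(3):
        syn = 0
        valid = 0
        for b in _BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1:]
            if alt in STOP_CODONS:
                continue
            valid += 1
            if GENETIC_CODE[alt] == aa:
                syn += 1
        if valid:
            s += syn / valid
    return s, 3.0 - s


@lru_cache(maxsize=None)
def ng86_pair_diffs(codon_a: str, codon_b: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two codons,
    averaged over stop-free orderings of the minimal mutation path."""
    a = _check_codon(codon_a)
    b = _check_codon(codon_b)
    diff = [i for i in range(3) if a[i] != b[i]]
    if not diff:
        return 0.0, 0.0

    def path_counts(order) -> tuple[float, float, bool]:
        syn = nonsyn = 0
        cur = a
        blocked = False
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1:]
            if nxt in STOP_CODONS:
                blocked = True
            if GENETIC_CODE.get(nxt, "*") == GENETIC_CODE[cur]:
                syn += 1
            else:
                nonsyn += 1
            cur = nxt
        return syn, nonsyn, blocked

    all_paths = [path_counts(order) for order in permutations(diff)]
    open_paths = [p for p in all_paths if not p[2]]
    use = open_paths if open_paths else all_paths
    sd = sum(p[0] for p in use) / len(use)
    nd = sum(p[1] for p in use) / len(use)
    return sd, nd


def _jc_correct(p: float) -> tuple[float, bool]:
    """Jukes-Cantor distance; (nan, True) when saturated (p >= 3/4)."""
    if p >= 0.75:
        return float("nan"), True
    return -0.75 * math.log(1.0 - (4.0 / 3.0) * p), False


@dataclass(frozen=True)
class KaKsResult:
    syn_sites: float
    nonsyn_sites: float
    syn_diffs: float
    nonsyn_diffs: float
    ps: float
    pn: float
    ks: float
    ka: float
    ratio: float
    ratio_defined: bool
    saturated: bool
    n_codons: int

    @property
    def omega(self) -> float:
        return self.ratio


def _iter_codon_pairs(seq_a: str, seq_b: str):
    """Yield comparable codon pairs after codon-wise pairwise deletion.

    Codons containing a gap or ambiguous base in either row are dropped;
    a shared terminal stop codon is tolerated and dropped; an internal
    stop is an error.
    """
    a = seq_a.upper()
    b = seq_b.upper()
    if len(a) != len(b):
        raise ValueError("sequences differ in length")
    if len(a) % 3:
        raise ValueError("alignment length not divisible by 3")
    n = len(a) // 3
    for k in range(n):
        ca = a[3 * k: 3 * k + 3]
        cb = b[3 * k: 3 * k + 3]
        if (set(ca) | set(cb)) & _GAPPY:
            continue
        if set(ca + cb) - _VALID:
            continue
        if ca in STOP_CODONS or cb in STOP_CODONS:
            if k == n - 1:
                continue
            raise ValueError(f"internal stop codon at codon {k + 1}")
        yield ca, cb


def kaks_pair(seq_a: str, seq_b: str) -> KaKsResult:
    """NG86 Ka/Ks for one pairwise codon alignment.

    Site counts are averaged between the two sequences; differences are
    pathway-averaged.  The ratio is flagged undefined when Ks = 0.
    """
    s_sites = n_sites = sd = nd = 0.0
    n_codons = 0
    for ca, cb in _iter_codon_pairs(seq_a, seq_b):
        n_codons += 1
        sa, na = ng86_codon_sites(ca)
        sb, nb = ng86_codon_sites(cb)
        s_sites += 0.5 * (sa + sb)
        n_sites += 0.5 * (na + nb)
        d = ng86_pair_diffs(ca, cb)
        sd += d[0]
        nd += d[1]
    if n_codons == 0:
        raise ValueError("no comparable codons")
    ps = sd / s_sites if s_sites > 0 else 0.0
    pn = nd / n_sites if n_sites > 0 else 0.0
    ks, sat_s = _jc_correct(ps)
    ka, sat_n = _jc_correct(pn)
    saturated = sat_s or sat_n
    if not saturated and ks > 0:
        ratio, defined = ka / ks, True
    else:
        ratio, defined = float("nan"), False
    return KaKsResult(
        syn_sites=s_sites,
        nonsyn_sites=n_sites,
        syn_diffs=sd,
        nonsyn_diffs=nd,
        ps=ps,
        pn=pn,
        ks=ks,
        ka=ka,
        ratio=ratio,
        ratio_defined=defined,
        saturated=saturated,
        n_codons=n_codons,
    )


@dataclass(frozen=True)
class Window:
    start: int      # 1-based bp, inclusive
    midpoint: float
    end: int        # 1-based bp, inclusive
    result: KaKsResult


@dataclass(frozen=True)
class KaKsProfile:
    windows: tuple[Window, ...]
    window_size: int
    step: int

    def as_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "window_start": w.start,
                    "midpoint": w.midpoint,
                    "window_end": w.end,
                    "ka": w.result.ka,
                    "ks": w.result.ks,
                    "ratio": w.result.ratio,
                    "ratio_defined": w.result.ratio_defined,
                    "saturated": w.result.saturated,
                }
                for w in self.windows
            ]
        )


def sliding_window(
    seq_a: str, seq_b: str, window: int = 150, step: int = 9
) -> KaKsProfile:
    """Ka/Ks profile along the alignment (coordinates 1-based bp)."""
    if window % 3 or step % 3:
        raise ValueError("window and step must be multiples of 3")
    length = len(seq_a)
    if len(seq_b) != length:
        raise ValueError("sequences differ in length")
    if length < window:
        raise ValueError("alignment shorter than the window")
    windows = []
    n_win = (length - window) // step + 1
    for i in range(n_win):
        start = i * step  # 0-based bp
        res = kaks_pair(seq_a[start: start + window], seq_b[start: start + window])
        windows.append(
            Window(
                start=start + 1,
                midpoint=start + (window + 1) / 2.0,
                end=start + window,
                result=res,
            )
        )
    return KaKsProfile(tuple(windows), window, step)


def region_kaks(seq_a: str, seq_b: str, region: tuple[int, int]) -> KaKsResult:
    """Ka/Ks restricted to a codon interval [start, end), 0-based."""
    start, end = region
    n = len(seq_a) // 3
    if not (0 <= start < end <= n):
        raise ValueError(f"region {region} outside alignment of {n} codons")
    return kaks_pair(seq_a[3 * start: 3 * end], seq_b[3 * start: 3 * end])


def kruskal_wallis(*groups) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) and chi-square p, df = k - 1.

    NaN entries (undefined ratios) are dropped with a logged count; if all
    values are identical H = 0, p = 1.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    cleaned = []
    dropped = 0
    for g in groups:
        arr = np.asarray(list(g), dtype=float)
        keep = arr[~np.isnan(arr)]
        dropped += len(arr) - len(keep)
        if len(keep) == 0:
            raise ValueError("a group has no defined values")
        cleaned.append(keep)
    if dropped:
        logger.info("kruskal_wallis: dropped %d undefined ratios", dropped)
    if sum(len(g) for g in cleaned) < 3:
        raise ValueError("need at least three values in total")
    flat = np.concatenate(cleaned)
    if np.all(flat == flat[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*cleaned)
    return float(h), float(p)


# -- table-driven fast path (batch estimation on encoded codons) ----------


_TABLES = None


def _pair_tables():
    """Precomputed per-codon sites and per-pair differences over the 61
    sense codons, used by :func:`kaks_from_codon_indices`."""
    global _TABLES
    if _TABLES is None:
        from .synthetic import SENSE_CODONS

        n = len(SENSE_CODONS)
        s_sites = np.empty(n)
        n_sites = np.empty(n)
        for i, c in enumerate(SENSE_CODONS):
            s_sites[i], n_sites[i] = ng86_codon_sites(c)
        sd = np.zeros((n, n))
        nd = np.zeros((n, n))
        for i, ci in enumerate(SENSE_CODONS):
            for j, cj in enumerate(SENSE_CODONS):
                sd[i, j], nd[i, j] = ng86_pair_diffs(ci, cj)
        _TABLES = (s_sites, n_sites, sd, nd)
    return _TABLES


def kaks_from_codon_indices(a: np.ndarray, b: np.ndarray) -> KaKsResult:
    """Vectorised NG86 on sense-codon index arrays (simulation output)."""
    s_tab, n_tab, sd_tab, nd_tab = _pair_tables()
    s_sites = float(0.5 * (s_tab[a] + s_tab[b]).sum())
    n_sites = float(0.5 * (n_tab[a] + n_tab[b]).sum())
    sd = float(sd_tab[a, b].sum())
    nd = float(nd_tab[a, b].sum())
    ps = sd / s_sites if s_sites > 0 else 0.0
    pn = nd / n_sites if n_sites > 0 else 0.0
    ks, sat_s = _jc_correct(ps)
    ka, sat_n = _jc_correct(pn)
    saturated = sat_s or sat_n
    if not saturated and ks > 0:
        ratio, defined = ka / ks, True
    else:
        ratio, defined = float("nan"), False
    return KaKsResult(
        syn_sites=s_sites,
        nonsyn_sites=n_sites,
        syn_diffs=sd,
        nonsyn_diffs=nd,
        ps=ps,
        pn=pn,
        ks=ks,
        ka=ka,
        ratio=ratio,
        ratio_defined=defined,
        saturated=saturated,
        n_codons=len(a),
    )
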