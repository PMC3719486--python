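"""JTT amino-acid substitution model and maximum-likelihood distances.

The model is the Jones-Taylor-Thornton (1992) empirical exchangeability
matrix with its published equilibrium frequencies.  The instantaneous rate
matrix is Q = S.diag(pi), normalised so that the expected number of
substitutions per site per unit time at equilibrium is 1; a pairwise ML
distance is then the time t maximising the likelihood of the observed
residue pairs under P(t) = expm(Q t) with stationary start probabilities.

Distances are in amino-acid substitutions per site, capped at
``SATURATION_CAP`` (estimates at the cap are flagged saturated).
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = [
    "AA_ORDER",
    "AA_INDEX",
    "SATURATION_CAP",
    "transition_probs",
    "pair_counts",
    "ml_distance_from_counts",
    "p_distance_from_counts",
    "poisson_distance_from_counts",
    "grid_ml_distances",
]

AA_ORDER = "ARNDCQEGHILKMFPSTWYV"
AA_INDEX = {a: i for i, a in enumerate(AA_ORDER)}

SATURATION_CAP = 10.0

# Published JTT exchangeabilities, lower triangle column-major in AA_ORDER
# (column j, rows i>j), and equilibrium frequencies.
_JTT_EXCH = [
    58, 54, 81, 56, 57, 105, 179, 27, 36, 30, 35, 54, 15, 194, 378, 475, 9,
    11, 298, 45, 16, 113, 310, 29, 137, 328, 22, 38, 646, 44, 5, 74, 101, 64,
    126, 20, 17, 528, 34, 86, 58, 81, 391, 47, 12, 263, 30, 10, 15, 503, 232,
    8, 70, 16, 10, 49, 767, 130, 112, 11, 7, 26, 15, 4, 15, 59, 38, 4, 46,
    31, 9, 5, 59, 69, 17, 23, 7, 31, 78, 14, 223, 42, 115, 209, 62, 323, 26,
    597, 9, 72, 292, 43, 4, 164, 53, 51, 18, 24, 20, 119, 26, 12, 9, 181, 18,
    5, 18, 30, 32, 10, 7, 45, 23, 6, 6, 27, 14, 5, 24, 201, 33, 55, 8, 47,
    16, 56, 45, 33, 40, 115, 73, 46, 8, 573, 11, 229, 21, 479, 89, 10, 40,
    245, 9, 32, 961, 14, 388, 248, 102, 59, 25, 52, 24, 180, 65, 4, 21, 47,
    103, 10, 8, 14, 43, 16, 29, 226, 24, 18, 323, 17, 92, 12, 53, 536, 62,
    285, 118, 6, 10, 23, 477, 35, 63, 38, 12, 21, 112, 71, 25, 16,
]
JTT_FREQS = np.array([
    0.076748, 0.051691, 0.042645, 0.051544, 0.019803, 0.040752, 0.061830,
    0.073152, 0.022944, 0.053761, 0.091904, 0.058676, 0.023826, 0.040126,
    0.050901, 0.068765, 0.058565, 0.014261, 0.032102, 0.066005,
])
JTT_FREQS = JTT_FREQS / JTT_FREQS.sum()


def _build_model():
    s = np.zeros((20, 20))
    k = 0
    for j in range(19):
        for i in range(j + 1, 20):
            s[i, j] = s[j, i] = _JTT_EXCH[k]
            k += 1
    pi = JTT_FREQS
    q = s * pi[None, :]
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    # normalise: one expected substitution per site per unit time
    q /= -(pi * np.diag(q)).sum()
    # symmetric decomposition: B = D^1/2 Q D^-1/2 is symmetric
    sq = np.sqrt(pi)
    b = (q * sq[:, None]) / sq[None, :]
    w, v = np.linalg.eigh((b + b.T) / 2.0)
    # P(t) = D^-1/2 V exp(w t) V' D^1/2
    left = v / sq[:, None]
    right = (v * sq[:, None]).T
    return q, w, left, right


_Q, _EIGVALS, _LEFT, _RIGHT = _build_model()


def transition_probs(t: float) -> np.ndarray:
    """P(t) = expm(Q t), rows indexed by AA_ORDER."""
    if t < 0:
        raise ValueError("time must be non-negative")
    p = (_LEFT * np.exp(_EIGVALS * t)) @ _RIGHT
    return np.clip(p, 0.0, None)


def encode(row: str) -> np.ndarray:
    """Residue string -> int codes (0..19; 20 for gap/unknown)."""
    out = np.fromiter((AA_INDEX.get(c, 20) for c in row.upper()), dtype=np.int64)
    return out


def pair_counts(row_a: str, row_b: str) -> np.ndarray:
    """20x20 residue-pair counts after pairwise deletion of gap columns."""
    if len(row_a) != len(row_b):
        raise ValueError("rows differ in length")
    a = encode(row_a)
    b = encode(row_b)
    ok = (a < 20) & (b < 20)
    if not ok.any():
        raise ValueError("no shared sites")
    joint = a[ok] * 20 + b[ok]
    return np.bincount(joint, minlength=400).reshape(20, 20).astype(float)


def _loglik(counts: np.ndarray, t: float) -> float:
    # joint likelihood pi_i * P_ij(t); reversibility makes it symmetric
    p = transition_probs(t) * JTT_FREQS[:, None]
    with np.errstate(divide="ignore"):
        lp = np.log(np.clip(p, 1e-300, None))
    return float((counts * lp).sum())


def ml_distance_from_counts(counts: np.ndarray) -> tuple[float, bool]:
    """(distance, saturated) maximising the JTT likelihood; cap at 10.0."""
    n = counts.sum()
    if n == 0:
        raise ValueError("no shared sites")
    mismatches = n - np.trace(counts)
    if mismatches == 0:
        return 0.0, False
    res = minimize_scalar(
        lambda t: -_loglik(counts, t),
        bounds=(1e-9, SATURATION_CAP),
        method="bounded",
        options={"xatol": 1e-7},
    )
    t = float(res.x)
    # bounded Brent never lands exactly on the bound; snap near-cap estimates
    if t > SATURATION_CAP - 1e-3:
        return SATURATION_CAP, True
    return t, False


def p_distance_from_counts(counts: np.ndarray) -> float:
    n = counts.sum()
    return float((n - np.trace(counts)) / n)


def poisson_distance_from_counts(counts: np.ndarray) -> tuple[float, bool]:
    """Poisson-corrected distance d = -ln(1-p); fallback estimator."""
    p = p_distance_from_counts(counts)
    if p >= 1.0 - 1e-12:
        return SATURATION_CAP, True
    d = -np.log(1.0 - p)
    if d >= SATURATION_CAP:
        return SATURATION_CAP, True
    return float(d), False


# -- fast batched estimation (bootstrap path) -----------------------------
#
# For bootstrap replicates the ML optimisation is done on a fixed log-spaced
# time grid with one parabolic refinement in log-time; the grid resolution
# (~2% in t) is far below what tree topology estimation can resolve, while
# the public ml_distance_from_counts keeps the 1e-6 Brent tolerance.

_GRID_SIZE = 160
_T_GRID = np.geomspace(1e-4, SATURATION_CAP, _GRID_SIZE)
_LOG_T_GRID = np.log(_T_GRID)
_LOGP_GRID = None


def _grid_tables():
    global _LOGP_GRID
    if _LOGP_GRID is None:
        tab = np.empty((_GRID_SIZE, 400))
        for i, t in enumerate(_T_GRID):
            joint = transition_probs(t) * JTT_FREQS[:, None]
            tab[i] = np.log(np.clip(joint, 1e-300, None)).ravel()
        _LOGP_GRID = tab
    return _LOGP_GRID


def grid_ml_distances(counts: np.ndarray) -> np.ndarray:
    """Approximate ML distances for a batch of count matrices.

    ``counts`` has shape (n_pairs, 20, 20); returns distances (n_pairs,)
    capped at SATURATION_CAP.
    """
    tab = _grid_tables()
    flat = counts.reshape(len(counts), 400)
    ll = flat @ tab.T  # (n_pairs, grid)
    best = np.argmax(ll, axis=1)
    dist = _T_GRID[best].copy()
    inner = (best > 0) & (best < _GRID_SIZE - 1)
    if inner.any():
        i = best[inner]
        rows = np.nonzero(inner)[0]
        y0 = ll[rows, i - 1]
        y1 = ll[rows, i]
        y2 = ll[rows, i + 1]
        x0, x1, x2 = _LOG_T_GRID[i - 1], _LOG_T_GRID[i], _LOG_T_GRID[i + 1]
        denom = (y0 - 2 * y1 + y2)
        with np.errstate(divide="ignore", invalid="ignore"):
            shift = 0.5 * (y0 - y2) / denom
        shift = np.where(np.isfinite(shift), np.clip(shift, -1, 1), 0.0)
        dist[inner] = np.exp(x1 + shift * (x2 - x1))
    # identical rows -> exact zero
    n = flat.sum(axis=1)
    ident = (n - np.trace(counts, axis1=1, axis2=2)) == 0
    dist[ident] = 0.0
    return np.minimum(dist, SATURATION_CAP)
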