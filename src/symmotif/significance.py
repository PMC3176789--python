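"""Statistical significance of motif information content, and E-values.

The information content of a motif built from n random background
sequences has a computable null distribution: a single column's counts are
Multinomial(n, background), and its information

    I_col = sum_b (n_b / n) log2( n_b / (n p_b) )

is a discrete statistic whose full distribution is obtained by dynamic
programming over the four bases with states (letters placed, score bin),
entirely in natural-log space so that probabilities as small as e^-2000
remain representable.  The L-column total is the L-fold convolution of the
column distribution, and the p-value of an observed information I_obs is
the upper tail P(I_total >= I_obs).

E-values additionally account for the number of possible alignments of the
input.  A search that may use each of N sites in either orientation has
2^N candidate alignments, so its E-value is p * 2^N; a symmetric-mode fit
has exactly one alignment (both orientations enter simultaneously).  The
symmetric-mode null is NOT L independent columns: symmetrizing ties each
column to its complement-mirror partner, so the matrix has floor(L/2) free
column pairs (each pair's information counted twice, built from 2N
letters) plus, for odd L, a self-symmetrized central column.  The
symmetric p-value is computed from that constrained null.

All reports carry -ln(E-value), so larger is more significant, and model
selection simply keeps the mode with the larger -ln(E-value).
"""
from __future__ import annotations

import dataclasses
import functools
import math

import numpy as np
from scipy.special import gammaln, logsumexp
from scipy.stats import binom

from .motif_discovery import MotifModel, information_content

UNIFORM = (0.25, 0.25, 0.25, 0.25)
_LN2 = math.log(2.0)

#: Memory guard for the DP lattice (states = (n+1) * score bins).
_MAX_STATES = 8e7


@dataclasses.dataclass(eq=False)
class NullDistribution:
    """Binned log-probability mass of an information statistic.

    Bin i covers information i * bin_width bits; bin 0 is exactly zero
    information.  ``n`` is the number of letters per column and ``width``
    the number of columns convolved (1 for a single column).
    """

    log_probs: np.ndarray
    bin_width: float
    n: int
    width: int
    background: tuple

    @property
    def max_bits(self) -> float:
        return (len(self.log_probs) - 1) * self.bin_width

    def log_sf(self, i_obs: float) -> float:
        """ln P(I >= i_obs); exactly 0.0 at i_obs <= 0, monotone in i_obs."""
        idx = int(round(i_obs / self.bin_width))
        if idx <= 0:
            return 0.0
        if idx >= len(self.log_probs):
            return -math.inf
        return float(min(0.0, logsumexp(self.log_probs[idx:])))


def _validated_background(background) -> tuple:
    bg = tuple(float(p) for p in background)
    if len(bg) != 4 or any(p <= 0 for p in bg):
        raise ValueError("background must be four positive probabilities")
    if abs(sum(bg) - 1.0) > 1e-9:
        raise ValueError("background probabilities must sum to 1")
    return bg


@functools.lru_cache(maxsize=32)
def _column_distribution_cached(n: int, background: tuple, bin_width: float) -> NullDistribution:
    p = np.asarray(background)
    kk = np.arange(n + 1)
    lgk = gammaln(kk + 1.0)
    # Partial sums over a subset of bases can dip below zero (single-base
    # terms x log2(x/p) reach -p log2(e)/e), but never below -0.54 bits for
    # a probability vector; the full column score is a KL divergence >= 0.
    neg = int(np.ceil(0.6 / bin_width))
    max_bits = float(np.max(np.log2(1.0 / p)))
    top = int(np.ceil(max_bits / bin_width)) + 4
    S = neg + top + 1
    if (n + 1) * S > _MAX_STATES:
        raise MemoryError(
            f"DP lattice of {(n + 1) * S:.2g} states exceeds the guard; "
            "use a larger bin_width"
        )
    weights = []
    dbins = []
    for b in range(4):
        w = kk * math.log(p[b]) - lgk
        delta = np.zeros(n + 1)
        delta[1:] = (kk[1:] / n) * np.log2(kk[1:] / (n * p[b]))
        weights.append(w)
        dbins.append(np.rint(delta / bin_width).astype(np.int64))

    # base 0 seeds the lattice; bases 1-2 convolve; base 3's count is forced
    dp = np.full((n + 1, S), -np.inf)
    dp[kk, neg + dbins[0]] = weights[0]
    for b in (1, 2):
        new = np.full((n + 1, S), -np.inf)
        w, db = weights[b], dbins[b]
        for k in range(n + 1):
            rows = n + 1 - k
            sh = int(db[k])
            if sh >= 0:
                tgt = new[k:k + rows, sh:]
                src = dp[:rows, :S - sh]
            elif sh < 0:
                tgt = new[k:k + rows, :sh]
                src = dp[:rows, -sh:]
            np.logaddexp(tgt, src + w[k], out=tgt)
        dp = new
    out = np.full(S, -np.inf)
    w, db = weights[3], dbins[3]
    for m in range(n + 1):
        k = n - m
        sh = int(db[k])
        if sh >= 0:
            seg = out[sh:]
            np.logaddexp(seg, dp[m, :S - sh] + w[k], out=seg)
        else:
            seg = out[:sh]
            np.logaddexp(seg, dp[m, -sh:] + w[k], out=seg)
    out += gammaln(n + 1.0)

    # fold per-base rounding spill below zero back into the zero bin
    log_probs = np.concatenate(([logsumexp(out[: neg + 1])], out[neg + 1:]))
    total = logsumexp(log_probs)
    if abs(total) > 1e-9:
        raise AssertionError(
            f"column null distribution mass {math.exp(total)} != 1"
        )
    log_probs = log_probs - total
    finite = np.nonzero(np.isfinite(log_probs))[0]
    log_probs = log_probs[: finite[-1] + 1]
    log_probs.setflags(write=False)
    return NullDistribution(log_probs, bin_width, n, 1, background)


def column_score_distribution(
    n: int, background=UNIFORM, bin_width: float = 0.005
) -> NullDistribution:
    """Null distribution of a single column's information (n letters).

    Exact up to score binning: each base's contribution is rounded to the
    nearest ``bin_width`` before accumulation, which defines the bin a
    count vector falls into.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    return _column_distribution_cached(n, _validated_background(background), float(bin_width))


def _log_convolve(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Log-space convolution of two binned log-mass vectors."""
    if len(b) > len(a):
        a, b = b, a
    out = np.full(len(a) + len(b) - 1, -np.inf)
    for j in np.nonzero(np.isfinite(b))[0]:
        seg = out[j:j + len(a)]
        np.logaddexp(seg, a + b[j], out=seg)
    return out


@functools.lru_cache(maxsize=64)
def _total_distribution_cached(
    n: int, width: int, background: tuple, bin_width: float
) -> NullDistribution:
    col = _column_distribution_cached(n, background, bin_width)
    total = col.log_probs.copy()
    for _ in range(width - 1):
        total = _log_convolve(total, col.log_probs)
    total.setflags(write=False)
    return NullDistribution(total, bin_width, n, width, background)


def log_pvalue_information(
    i_obs: float,
    n: int,
    width: int,
    background=UNIFORM,
    bin_width: float = 0.005,
) -> float:
    """ln P(I_total >= i_obs) for ``width`` independent columns of n letters.

    Monotone nonincreasing in ``i_obs``; exactly 0 at i_obs = 0.
    """
    bg = _validated_background(background)
    max_total = width * float(np.max(np.log2(1.0 / np.asarray(bg))))
    if i_obs < -1e-9 or i_obs > max_total + 1e-9:
        raise ValueError(
            f"observed information {i_obs} outside [0, {max_total}] bits"
        )
    dist = _total_distribution_cached(n, width, bg, float(bin_width))
    return dist.log_sf(i_obs)


@functools.lru_cache(maxsize=32)
def _center_column_distribution(
    n_sites: int, background: tuple, bin_width: float
) -> NullDistribution:
    """Null information of a self-symmetrized central column.

    From N background letters the symmetrized column holds 2N letters with
    counts (W, N-W, N-W, W) for W = #A + #T ~ Binomial(N, p_A + p_T).
    """
    p = background
    N = n_sites
    q = p[0] + p[3]
    W = np.arange(N + 1)
    log_pmf = binom.logpmf(W, N, q)
    fA = W / (2.0 * N)
    fC = (N - W) / (2.0 * N)
    with np.errstate(divide="ignore", invalid="ignore"):
        score = (
            np.where(fA > 0, fA * (np.log2(fA / p[0]) + np.log2(fA / p[3])), 0.0)
            + np.where(fC > 0, fC * (np.log2(fC / p[1]) + np.log2(fC / p[2])), 0.0)
        )
    bins = np.maximum(np.rint(score / bin_width).astype(np.int64), 0)
    out = np.full(int(bins.max()) + 1, -np.inf)
    np.logaddexp.at(out, bins, log_pmf)
    out.setflags(write=False)
    return NullDistribution(out, bin_width, 2 * N, 1, background)


@functools.lru_cache(maxsize=64)
def _symmetric_distribution_cached(
    n_sites: int, width: int, background: tuple, bin_width: float
) -> NullDistribution:
    p = background
    if abs(p[0] - p[3]) > 1e-12 or abs(p[1] - p[2]) > 1e-12:
        raise ValueError(
            "symmetric-mode null requires a complement-symmetric background "
            "(p_A == p_T and p_C == p_G)"
        )
    pairs = width // 2
    total = None
    if pairs:
        col = _column_distribution_cached(2 * n_sites, background, bin_width)
        # each free column pair contributes its information twice
        doubled = np.full(2 * len(col.log_probs) - 1, -np.inf)
        doubled[::2] = col.log_probs
        total = doubled
        for _ in range(pairs - 1):
            total = _log_convolve(total, doubled)
    if width % 2 == 1:
        center = _center_column_distribution(n_sites, background, bin_width)
        total = (
            center.log_probs.copy()
            if total is None
            else _log_convolve(total, center.log_probs)
        )
    total.setflags(write=False)
    return NullDistribution(total, bin_width, 2 * n_sites, width, background)


def log_pvalue_symmetric(
    i_obs: float,
    n_sites: int,
    width: int,
    background=UNIFORM,
    bin_width: float = 0.005,
) -> float:
    """ln p-value for a symmetric-mode motif of ``width`` columns, N sites.

    The null statistic is 2 * sum of floor(L/2) free-column informations
    (2N letters each) plus the central-column term for odd L.
    """
    bg = _validated_background(background)
    dist = _symmetric_distribution_cached(n_sites, width, bg, float(bin_width))
    return dist.log_sf(i_obs)


@dataclasses.dataclass(frozen=True)
class SignificanceReport:
    """Information content, tail p-value and alignment-corrected E-value."""

    mode: str
    width: int
    information_bits: float
    log_pvalue: float           # natural log, <= 0
    n_alignments_log: float     # ln(number of possible alignments)
    minus_ln_evalue: float      # -(log_pvalue + n_alignments_log)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def evalue_report(
    model: MotifModel,
    *,
    background=None,
    bin_width: float = 0.005,
) -> SignificanceReport:
    """Significance of a discovered motif under its estimation mode.

    fixed:      one alignment, p-value with n = N independent columns.
    asymmetric: 2^N alignments (each site either orientation), n = N.
    symmetric:  one alignment, constrained null built from N sites.
    """
    bg = _validated_background(
        background if background is not None else model.background
    )
    i_obs = information_content(model, bg)
    L = model.width
    if model.mode == "asymmetric":
        n_sites = model.effective_n
        logp = log_pvalue_information(i_obs, n_sites, L, bg, bin_width)
        n_align_log = n_sites * _LN2
    elif model.mode == "fixed":
        logp = log_pvalue_information(i_obs, model.effective_n, L, bg, bin_width)
        n_align_log = 0.0
    elif model.mode == "symmetric":
        n_sites = model.effective_n // 2
        logp = log_pvalue_symmetric(i_obs, n_sites, L, bg, bin_width)
        n_align_log = 0.0
    else:
        raise ValueError(f"unknown motif mode {model.mode!r}")
    return SignificanceReport(
        model.mode, L, i_obs, logp, n_align_log, -(logp + n_align_log)
    )


@dataclasses.dataclass(frozen=True)
class ModelSelection:
    verdict: str  # "asymmetric" | "symmetric"
    margin: float  # |difference of -ln(E-value)|
    free_parameters: dict  # advisory parameter-count comparison

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def select_model(
    report_asym: SignificanceReport, report_sym: SignificanceReport
) -> ModelSelection:
    """Choose the mode with the larger -ln(E-value).

    Also reports the simpler parameter-count heuristic (a symmetric model
    of width L has ceil(L/2) free columns, i.e. 3*ceil(L/2) free
    parameters versus 3*L) as advisory output only.
    """
    if report_asym.width != report_sym.width:
        raise ValueError("reports compare motifs of different widths")
    L = report_asym.width
    if report_sym.minus_ln_evalue > report_asym.minus_ln_evalue:
        verdict = "symmetric"
    else:
        verdict = "asymmetric"
    margin = abs(report_sym.minus_ln_evalue - report_asym.minus_ln_evalue)
    params = {
        "asymmetric": 3 * L,
        "symmetric": 3 * math.ceil(L / 2),
    }
    return ModelSelection(verdict, margin, params)
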