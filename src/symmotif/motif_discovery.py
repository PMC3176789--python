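"""Motif estimation from aligned binding sites under three symmetry modes.

Because every input sequence is itself one site (no offsets, no gaps),
motif discovery reduces to choosing a strand orientation for each site and
counting bases.  Three modes are provided:

``fixed``
    Sites are taken as given.  Serves as the control: the only error left
    is sampling noise.

``asymmetric``
    Each site may be used in either orientation; orientations are chosen
    to maximize the information content of the resulting count matrix.
    For up to 12 sites the 2^N assignments are searched exhaustively;
    beyond that a seeded multi-restart coordinate ascent is used (flip one
    site's orientation whenever that strictly increases the information,
    sweep until stable).  On truly symmetric data this mode overfits: it
    orients each site toward its better-matching half and reports an
    inflated, asymmetric motif.

``symmetric``
    Every site contributes in both orientations, doubling the effective
    sample size to 2N and forcing the frequency matrix to equal its own
    reverse complement exactly.
"""
from __future__ import annotations

import dataclasses
import logging
import math
from collections.abc import Sequence

import numpy as np

from .energy_models import BASE_INDEX, BASES
from .synthetic_sites import SiteSample

logger = logging.getLogger(__name__)

FORWARD = "forward"
REVERSE = "reverse"
BOTH = "both"

_FLIP_TOL = 1e-9  # ties never flip, for cross-platform determinism


@dataclasses.dataclass(frozen=True)
class DiscoveryConfig:
    """Tunable parameters of motif estimation.

    ``pseudocount`` applies when frequencies are requested (0 keeps counts
    and information content pure); ``restarts``/``max_iterations``/``seed``
    steer the asymmetric-mode orientation search; ``background`` is the
    null base composition (uniform by default).
    """

    pseudocount: float = 0.0
    restarts: int = 20
    max_iterations: int = 100
    seed: int = 0
    background: tuple = (0.25, 0.25, 0.25, 0.25)
    method: str = "auto"  # auto | exhaustive | ascent

    def __post_init__(self) -> None:
        if abs(sum(self.background) - 1.0) > 1e-9:
            raise ValueError("background probabilities must sum to 1")
        if self.method not in ("auto", "exhaustive", "ascent"):
            raise ValueError(f"unknown search method {self.method!r}")


@dataclasses.dataclass(eq=False)
class MotifModel:
    """A count/frequency motif with its estimation mode and orientations."""

    mode: str  # fixed | asymmetric | symmetric
    counts: np.ndarray  # (L, 4), columns A,C,G,T; column sums == effective_n
    orientations: tuple[str, ...]
    effective_n: int
    background: tuple = (0.25, 0.25, 0.25, 0.25)
    converged: bool = True
    provenance: dict = dataclasses.field(default_factory=dict)

    @property
    def width(self) -> int:
        return self.counts.shape[0]

    def frequencies(self, pseudocount: float = 0.0) -> np.ndarray:
        """(count + pc) / (column total + 4 pc); columns sum to 1."""
        c = self.counts + pseudocount
        return c / c.sum(axis=1, keepdims=True)

    @property
    def consensus(self) -> str:
        return "".join(BASES[int(np.argmax(col))] for col in self.counts)


def _encode(sites: Sequence[str]) -> list[tuple[int, ...]]:
    rows = []
    for i, s in enumerate(sites):
        try:
            rows.append(tuple(BASE_INDEX[ch] for ch in s))
        except KeyError as exc:
            raise ValueError(f"site {i + 1} contains invalid base {exc}") from None
    return rows


def _rc_row(row: tuple[int, ...]) -> tuple[int, ...]:
    return tuple(3 - b for b in reversed(row))


def information_content(model: MotifModel, background=None) -> float:
    """Information content in bits: sum_j sum_b f log2(f / p_b), 0 log 0 := 0."""
    bg = np.asarray(background if background is not None else model.background)
    f = model.counts / model.effective_n
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(f > 0, f * np.log2(f / bg), 0.0)
    return float(terms.sum())


def build_pwm(
    sites: Sequence[str],
    orientations: Sequence[str],
    config: DiscoveryConfig | None = None,
    mode: str = "fixed",
) -> MotifModel:
    """Tally sites in their designated orientations into a count matrix."""
    if len(sites) == 0:
        raise ValueError("no sites provided")
    if len(orientations) != len(sites):
        raise ValueError("orientations must match sites in length")
    config = config or DiscoveryConfig()
    enc = _encode(sites)
    L = len(enc[0])
    if any(len(r) != L for r in enc):
        raise ValueError("sites must all have the same length")
    counts = np.zeros((L, 4))
    effective_n = 0
    for row, orient in zip(enc, orientations):
        use = []
        if orient in (FORWARD, BOTH):
            use.append(row)
        if orient in (REVERSE, BOTH):
            use.append(_rc_row(row))
        if not use:
            raise ValueError(f"unknown orientation {orient!r}")
        for r in use:
            for j, b in enumerate(r):
                counts[j, b] += 1
            effective_n += 1
    return MotifModel(
        mode, counts, tuple(orientations), effective_n, config.background
    )


def discover_fixed(sample: SiteSample, config: DiscoveryConfig | None = None) -> MotifModel:
    """Control mode: every site in its recorded (forward) orientation."""
    config = config or DiscoveryConfig()
    model = build_pwm(sample.sites, (FORWARD,) * sample.n, config, mode="fixed")
    model.provenance.update({"sample": sample.model_id})
    return model


def discover_symmetric(sample: SiteSample, config: DiscoveryConfig | None = None) -> MotifModel:
    """Symmetric mode: each site counted in both orientations (n -> 2N)."""
    config = config or DiscoveryConfig()
    fwd = build_pwm(sample.sites, (FORWARD,) * sample.n, config)
    counts = fwd.counts + fwd.counts[::-1, ::-1]
    model = MotifModel(
        "symmetric",
        counts,
        (BOTH,) * sample.n,
        2 * sample.n,
        config.background,
    )
    model.provenance.update({"sample": sample.model_id})
    return model


# -- asymmetric-mode orientation search -------------------------------------

def _score_tables(n_max: int, background: tuple) -> tuple[list, list]:
    # score(counts) = sum_j sum_b [c log2 c - c log2 p_b]; the information
    # content is score / N - L log2 N, so maximizing score maximizes I.
    g = [0.0] * (n_max + 1)
    for c in range(1, n_max + 1):
        g[c] = c * math.log2(c)
    lp = [math.log2(p) if p > 0 else -math.inf for p in background]
    return g, lp


def _score(counts: list[list[int]], g: list, lp: list) -> float:
    s = 0.0
    for col in counts:
        for b in range(4):
            c = col[b]
            s += g[c] - c * lp[b]
    return s


def _counts_from(rows, orients, L):
    counts = [[0] * 4 for _ in range(L)]
    for (fwd, rev), o in zip(rows, orients):
        row = rev if o else fwd
        for j in range(L):
            counts[j][row[j]] += 1
    return counts


def _ascend(rows, orients, L, g, lp, max_iterations):
    """Coordinate ascent over per-site orientation flips; ties rejected."""
    counts = _counts_from(rows, orients, L)
    converged = False
    for _ in range(max_iterations):
        changed = False
        for i, (fwd, rev) in enumerate(rows):
            cur = rev if orients[i] else fwd
            alt = fwd if orients[i] else rev
            delta = 0.0
            for j in range(L):
                br, ba = cur[j], alt[j]
                if br == ba:
                    continue
                cr = counts[j][br]
                ca = counts[j][ba]
                delta += g[cr - 1] - g[cr] + lp[br]
                delta += g[ca + 1] - g[ca] - lp[ba]
            if delta > _FLIP_TOL:
                orients[i] ^= 1
                for j in range(L):
                    br, ba = cur[j], alt[j]
                    if br != ba:
                        counts[j][br] -= 1
                        counts[j][ba] += 1
                changed = True
        if not changed:
            converged = True
            break
    return orients, counts, converged


def _canonicalize(rows, orients, counts, L):
    """Report the majority orientation as forward; break exact ties toward
    the lexicographically smaller consensus string."""
    n = len(orients)
    n_rev = sum(orients)
    flip = False
    if n_rev * 2 > n:
        flip = True
    elif n_rev * 2 == n:
        cons = "".join(BASES[max(range(4), key=lambda b: (col[b], -b))] for col in counts)
        rc_counts = [[col[3 - b] for b in range(4)] for col in reversed(counts)]
        cons_rc = "".join(
            BASES[max(range(4), key=lambda b: (col[b], -b))] for col in rc_counts
        )
        flip = cons_rc < cons
    if flip:
        orients = [1 - o for o in orients]
        counts = [[col[3 - b] for b in range(4)] for col in reversed(counts)]
    return orients, counts


def discover_asymmetric(sample: SiteSample, config: DiscoveryConfig | None = None) -> MotifModel:
    """Orientation-free mode: maximize information over per-site orientations.

    Exhaustive over all 2^N assignments for N <= 12 (or when forced via
    ``config.method``); otherwise seeded multi-restart coordinate ascent.
    Deterministic for a fixed seed.  The returned model is canonicalized so
    the orientation majority is forward.
    """
    config = config or DiscoveryConfig()
    enc = _encode(sample.sites)
    L = sample.width
    N = sample.n
    rows = [(row, _rc_row(row)) for row in enc]
    g, lp = _score_tables(N, config.background)

    exhaustive = config.method == "exhaustive" or (
        config.method == "auto" and N <= 12
    )
    converged = True
    if exhaustive:
        best_score = -math.inf
        best_orients = [0] * N
        for mask in range(1 << N):
            orients = [(mask >> i) & 1 for i in range(N)]
            s = _score(_counts_from(rows, orients, L), g, lp)
            if s > best_score + _FLIP_TOL:
                best_score = s
                best_orients = orients
        counts = _counts_from(rows, best_orients, L)
        provenance = {"search": "exhaustive", "assignments": 1 << N}
    else:
        rng = np.random.default_rng(config.seed)
        best_score = -math.inf
        best_orients = None
        counts = None
        n_unconverged = 0
        for r in range(max(1, config.restarts)):
            if r == 0:
                start = [0] * N
            else:
                start = [int(x) for x in rng.integers(0, 2, size=N)]
            orients, cts, ok = _ascend(
                rows, start, L, g, lp, config.max_iterations
            )
            if not ok:
                n_unconverged += 1
            s = _score(cts, g, lp)
            if s > best_score + _FLIP_TOL:
                best_score = s
                best_orients = orients
                counts = cts
        if n_unconverged:
            converged = False
            logger.warning(
                "discover_asymmetric: %d/%d restarts hit max_iterations=%d",
                n_unconverged, config.restarts, config.max_iterations,
            )
        provenance = {
            "search": "coordinate_ascent",
            "restarts": config.restarts,
            "seed": config.seed,
            "unconverged_restarts": n_unconverged,
        }

    best_orients, counts = _canonicalize(rows, best_orients, counts, L)
    orientations = tuple(REVERSE if o else FORWARD for o in best_orients)
    model = MotifModel(
        "asymmetric",
        np.array(counts, dtype=float),
        orientations,
        N,
        config.background,
        converged=converged,
        provenance={"sample": sample.model_id, **provenance},
    )
    return model
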