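"""Additive protein-DNA binding energy matrices and their symmetry structure.

A transcription factor's sequence specificity is modelled here as an
*additive energy matrix*: every position of a fixed-length site contributes
a base-dependent binding free energy (in kT units), and the energy of a site
is the sum of its per-position contributions.  The consensus base at each
position contributes 0, so the consensus sequence has energy 0 and every
other sequence a positive energy (weaker binding).

Many dimeric factors bind sites that are *reverse-complement symmetric*:
the energy matrix equals its own reverse complement ("even" symmetry for
even widths), or does so at every position pair except an unconstrained
central column ("odd" symmetry for odd widths).  This module provides the
matrix type, its symmetry operations (reverse complement, classification,
column swaps/deletions), degenerate-consensus utilities used by the HincII
demonstration, and a least-squares reconstruction of an additive matrix
from (site, energy) records.
"""
from __future__ import annotations

import dataclasses
import enum
import itertools
import logging
import math
from collections.abc import Sequence

import numpy as np

logger = logging.getLogger(__name__)

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT_TABLE = str.maketrans("ACGTacgt", "TGCAtgca")

#: 15-letter IUPAC nucleotide code (DNA only; U is not accepted).
IUPAC_CODES = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


class InvalidSequenceError(ValueError):
    """A sequence fails length or alphabet requirements."""


class FitError(RuntimeError):
    """Observed energies are not consistent with an additive model."""


def reverse_complement(sequence: str) -> str:
    """Reverse complement of a DNA string (case preserved)."""
    return sequence.translate(_COMPLEMENT_TABLE)[::-1]


def is_reverse_palindrome(sequence: str) -> bool:
    """True iff ``sequence`` equals its own reverse complement.

    Odd-length sequences can never be reverse-complement palindromes
    because the central base would have to equal its own complement.
    """
    _validate_dna(sequence)
    if len(sequence) % 2 == 1:
        return False
    return sequence == reverse_complement(sequence)


def expand_degenerate(iupac: str) -> set[str]:
    """Expand an IUPAC degenerate consensus into the set of concrete sites.

    >>> sorted(expand_degenerate("GTYRAC"))
    ['GTCAAC', 'GTCGAC', 'GTTAAC', 'GTTGAC']
    """
    choices = []
    for pos, ch in enumerate(iupac, start=1):
        try:
            choices.append(IUPAC_CODES[ch.upper()])
        except KeyError:
            raise InvalidSequenceError(
                f"unknown IUPAC character {ch!r} at position {pos}"
            ) from None
    return {"".join(letters) for letters in itertools.product(*choices)}


def _validate_dna(sequence: str) -> None:
    for pos, ch in enumerate(sequence, start=1):
        if ch not in BASE_INDEX:
            raise InvalidSequenceError(
                f"invalid base {ch!r} at position {pos}"
            )


class SymmetryClass(enum.Enum):
    ASYMMETRIC = "asymmetric"
    EVEN_SYMMETRIC = "even_symmetric"
    ODD_SYMMETRIC = "odd_symmetric"


@dataclasses.dataclass(frozen=True, eq=False)
class EnergyMatrix:
    """Additive per-position, per-base binding energies in kT units.

    ``energies`` has shape (L, 4) with columns ordered A, C, G, T.  Each
    position's minimum entry is 0 (the preferred base); all other entries
    are positive, so the consensus sequence scores exactly 0.  Entries may
    be NaN only when listed in ``undetermined`` (produced by
    :func:`fit_energy_matrix` when a base was never observed at a position).

    ``mu_default`` is the chemical potential associated with the model for
    occupancy calculations (see :mod:`symmotif.synthetic_sites`).
    """

    model_id: str
    energies: np.ndarray
    mu_default: float = -0.5
    undetermined: frozenset = frozenset()

    def __post_init__(self) -> None:
        arr = np.array(self.energies, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 4 or arr.shape[0] < 1:
            raise ValueError(
                f"energies must have shape (L, 4); got {arr.shape}"
            )
        undet = frozenset(self.undetermined)
        for j in range(arr.shape[0]):
            for b in range(4):
                if np.isnan(arr[j, b]) and (j + 1, BASES[b]) not in undet:
                    raise ValueError(
                        f"NaN energy at position {j + 1}, base {BASES[b]} "
                        "not flagged as undetermined"
                    )
            col = arr[j]
            if np.all(np.isnan(col)):
                raise ValueError(f"position {j + 1} has no determined entry")
            lo = np.nanmin(col)
            if lo < -1e-9 or lo > 1e-6:
                raise ValueError(
                    f"position {j + 1} minimum energy is {lo:.3g}; every "
                    "position must have a preferred base at exactly 0 kT"
                )
        arr.setflags(write=False)
        object.__setattr__(self, "energies", arr)
        object.__setattr__(self, "undetermined", undet)
        if not math.isfinite(self.mu_default):
            raise ValueError("mu_default must be finite")

    @property
    def width(self) -> int:
        return self.energies.shape[0]

    @property
    def consensus(self) -> str:
        """Minimum-energy sequence; ties broken toward A < C < G < T."""
        with np.errstate(invalid="ignore"):
            return "".join(BASES[int(np.nanargmin(col))] for col in self.energies)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EnergyMatrix):
            return NotImplemented
        return (
            self.width == other.width
            and np.array_equal(self.energies, other.energies, equal_nan=True)
        )

    def allclose(self, other: "EnergyMatrix", atol: float = 1e-9) -> bool:
        return self.width == other.width and np.allclose(
            self.energies, other.energies, atol=atol, equal_nan=True
        )


def site_energy(matrix: EnergyMatrix, sequence: str) -> float:
    """Additive binding energy of ``sequence`` under ``matrix`` (kT).

    The consensus sequence returns exactly 0 by the matrix invariant.
    """
    if len(sequence) != matrix.width:
        raise InvalidSequenceError(
            f"sequence length {len(sequence)} does not match matrix width "
            f"{matrix.width}"
        )
    total = 0.0
    for pos, ch in enumerate(sequence):
        idx = BASE_INDEX.get(ch)
        if idx is None:
            raise InvalidSequenceError(
                f"invalid base {ch!r} at position {pos + 1}"
            )
        e = matrix.energies[pos, idx]
        if np.isnan(e):
            raise InvalidSequenceError(
                f"energy undetermined for base {ch} at position {pos + 1} "
                f"of matrix {matrix.model_id!r}"
            )
        total += e
    return float(total)


def reverse_complement_matrix(matrix: EnergyMatrix) -> EnergyMatrix:
    """The matrix describing binding to the opposite strand.

    Entry (j, b) of the result equals entry (L+1-j, complement(b)) of the
    input, so for every sequence s: E_out(s) == E_in(reverse_complement(s)).
    Applying the operation twice returns the original matrix.
    """
    # With columns ordered A,C,G,T the complement is index reversal (3 - i).
    rc = matrix.energies[::-1, ::-1]
    L = matrix.width
    undet = frozenset(
        (L + 1 - pos, BASES[3 - BASE_INDEX[b]]) for pos, b in matrix.undetermined
    )
    return EnergyMatrix(matrix.model_id, rc, matrix.mu_default, undet)


def classify_symmetry(matrix: EnergyMatrix, atol: float = 1e-9) -> SymmetryClass:
    """Classify a matrix as asymmetric, even symmetric or odd symmetric.

    Even symmetry (even width only): the matrix equals its reverse
    complement.  Odd symmetry (odd width only): every position pair
    (j, L+1-j) with j != center is complement-mirrored while the central
    column is unconstrained.
    """
    rc = reverse_complement_matrix(matrix).energies
    L = matrix.width
    if L % 2 == 0:
        if np.allclose(matrix.energies, rc, atol=atol, equal_nan=True):
            return SymmetryClass.EVEN_SYMMETRIC
        return SymmetryClass.ASYMMETRIC
    center = L // 2  # 0-based central column
    rows = [j for j in range(L) if j != center]
    if np.allclose(matrix.energies[rows], rc[rows], atol=atol, equal_nan=True):
        return SymmetryClass.ODD_SYMMETRIC
    return SymmetryClass.ASYMMETRIC


def swap_positions(matrix: EnergyMatrix, j: int, k: int) -> EnergyMatrix:
    """Exchange columns j and k (1-based positions)."""
    L = matrix.width
    for pos in (j, k):
        if not 1 <= pos <= L:
            raise ValueError(f"position {pos} out of range 1..{L}")
    order = list(range(L))
    order[j - 1], order[k - 1] = order[k - 1], order[j - 1]
    remap = {j: k, k: j}
    undet = frozenset(
        (remap.get(pos, pos), b) for pos, b in matrix.undetermined
    )
    return EnergyMatrix(
        matrix.model_id, matrix.energies[order], matrix.mu_default, undet
    )


def delete_position(matrix: EnergyMatrix, j: int) -> EnergyMatrix:
    """Remove column j (1-based), reducing the width by one."""
    L = matrix.width
    if not 1 <= j <= L:
        raise ValueError(f"position {j} out of range 1..{L}")
    keep = [p for p in range(L) if p != j - 1]
    undet = frozenset(
        (pos - 1 if pos > j else pos, b)
        for pos, b in matrix.undetermined
        if pos != j
    )
    return EnergyMatrix(
        matrix.model_id, matrix.energies[keep], matrix.mu_default, undet
    )


def make_variant(matrix: EnergyMatrix, transform: str, *positions: int) -> EnergyMatrix:
    """Apply a named column transform: ``"swap"`` (j, k) or ``"delete"`` (j)."""
    if transform == "swap":
        return swap_positions(matrix, *positions)
    if transform == "delete":
        return delete_position(matrix, *positions)
    raise ValueError(f"unknown transform {transform!r}")


def fit_energy_matrix(
    sites: Sequence[str],
    energies: Sequence[float],
    *,
    model_id: str = "fitted",
    mu: float = -0.5,
    tol: float = 1e-6,
) -> EnergyMatrix:
    """Reconstruct an additive energy matrix from (site, energy) records.

    Solves the additive model by least squares and fixes the gauge by
    shifting each column so its minimum determined entry is 0.  If the
    input energies are exactly additive in that gauge (as for records
    written by the synthetic generator) the generating matrix is recovered
    exactly and every input energy is reproduced.

    Raises :class:`FitError` when residuals exceed ``tol`` (energies not
    additive).  Base/position combinations never observed in ``sites`` are
    flagged in the result's ``undetermined`` set and stored as NaN.
    """
    if len(sites) == 0:
        raise ValueError("no sites provided")
    if len(sites) != len(energies):
        raise ValueError("sites and energies differ in length")
    L = len(sites[0])
    n = len(sites)
    X = np.zeros((n, 4 * L))
    for i, s in enumerate(sites):
        if len(s) != L:
            raise InvalidSequenceError(
                f"site {i + 1} has length {len(s)}, expected {L}"
            )
        _validate_dna(s)
        for j, ch in enumerate(s):
            X[i, 4 * j + BASE_INDEX[ch]] = 1.0
    y = np.asarray(energies, dtype=float)
    observed = X.any(axis=0)
    beta_obs, *_ = np.linalg.lstsq(X[:, observed], y, rcond=None)
    resid = X[:, observed] @ beta_obs - y
    max_resid = float(np.max(np.abs(resid))) if n else 0.0
    if max_resid > tol * max(1.0, float(np.max(np.abs(y)))):
        raise FitError(
            f"energies are not additive: max residual {max_resid:.3g} "
            f"exceeds tolerance {tol:.3g}"
        )
    beta = np.full(4 * L, np.nan)
    beta[observed] = beta_obs
    E = beta.reshape(L, 4)
    undetermined = set()
    for j in range(L):
        E[j] -= np.nanmin(E[j])
        # clip tiny negative round-off so the gauge invariant holds exactly
        E[j] = np.where(np.abs(E[j]) < 1e-12, 0.0, E[j])
        for b in range(4):
            if np.isnan(E[j, b]):
                undetermined.add((j + 1, BASES[b]))
    if undetermined:
        logger.warning(
            "fit_energy_matrix: %d matrix entries undetermined (base never "
            "observed at that position)", len(undetermined)
        )
    return EnergyMatrix(model_id, E, mu, frozenset(undetermined))


# ---------------------------------------------------------------------------
# Default Mnt-like model family
#
# Eight models in two width classes.  The 7-long symmetric models have the
# odd-symmetric consensus GTGSCAC (S = G/C, the unconstrained centre);
# swapping positions 5 and 6 yields the Mnt-like asymmetric consensus
# GTGGACC.  Deleting the centre position gives the 6-long pairs GTGCAC
# (even symmetric) and GTGACC (asymmetric).  The "-2" variants differ from
# "-1" in the base assignment at position 2 and in a less specific centre
# column, which weakens the orientation signal of individual sites.

DEFAULT_MODEL_IDS = (
    "M7A-1", "M7A-2", "M6A-1", "M6A-2",
    "M7S-1", "M7S-2", "M6S-1", "M6S-2",
)

_COL1 = (0.15, 0.25, 0.0, 0.1)  # G weakly preferred flank
_COL2 = {
    "1": (3.2, 2.6, 2.55, 0.0),  # T preferred; affinity ranks T,G > C,A
    "2": (2.55, 2.6, 3.2, 0.0),  # T preferred; affinity ranks T,A > C,G
}
_COL3 = (1.2, 0.5, 0.0, 3.3)  # G preferred, T strongly disfavoured
_CENTER = {
    "1": (0.3, 0.1, 0.0, 0.3),    # G slightly preferred over C
    "2": (0.15, 0.04, 0.0, 0.15),  # weaker discrimination in the centre
}


def _mirror(col: tuple) -> tuple:
    # energy of base b in the complement-mirrored column equals the energy
    # of complement(b) in the source column; complement reverses A,C,G,T
    return col[::-1]


def default_matrix(model_id: str, mu: float = -0.5) -> EnergyMatrix:
    """One of the eight shipped Mnt-like true-motif energy matrices."""
    if model_id not in DEFAULT_MODEL_IDS:
        raise KeyError(
            f"unknown model id {model_id!r}; expected one of "
            f"{', '.join(DEFAULT_MODEL_IDS)}"
        )
    variant = model_id[-1]
    c1, c2, c3 = _COL1, _COL2[variant], _COL3
    center = _CENTER[variant]
    sym7 = [c1, c2, c3, center, _mirror(c3), _mirror(c2), _mirror(c1)]
    m7s = EnergyMatrix(model_id, np.array(sym7), mu)
    if model_id.startswith("M7S"):
        return m7s
    m7a = dataclasses.replace(swap_positions(m7s, 5, 6), model_id=model_id)
    if model_id.startswith("M7A"):
        return m7a
    base7 = m7a if model_id.startswith("M6A") else m7s
    return dataclasses.replace(delete_position(base7, 4), model_id=model_id)


def default_models(mu: float = -0.5) -> dict[str, EnergyMatrix]:
    return {mid: default_matrix(mid, mu) for mid in DEFAULT_MODEL_IDS}
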