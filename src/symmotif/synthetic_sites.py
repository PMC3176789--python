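"""Sequence-landscape enumeration and Boltzmann-occupancy site sampling.

The probability that a DNA-binding protein occupies a site with binding
energy E (kT) is given by the standard biophysical (Fermi-Dirac) model

    theta(E) = 1 / (1 + exp(E - mu)),

where mu is the chemical potential of the protein, a stand-in for its
concentration.  At the default operating point mu = -0.5 the consensus
sequence (E = 0) is bound with probability ~0.38, low enough that the
occupancy of every other sequence is very nearly proportional to its
Boltzmann factor exp(-E).

Binding-site collections are simulated by enumerating the complete
landscape of all 4^L L-mers, converting energies to occupancies, and
drawing sites i.i.d. from the normalized occupancy distribution
pi_i = theta(E_i) / sum_j theta(E_j).  Samples carry their true energies
and full provenance (matrix, mu, seed) so every downstream table can be
regenerated byte-identically.
"""
from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
from scipy.special import expit

from . import __version__
from .energy_models import (
    BASES,
    EnergyMatrix,
    InvalidSequenceError,
    site_energy,
)

logger = logging.getLogger(__name__)

#: Hard guard on landscape enumeration (4^12 ~ 16.8M records).
MAX_WIDTH = 12


class SampleFileError(ValueError):
    """A site-sample file is malformed; the message names the line."""


def occupancy(energy, mu: float = -0.5):
    """Fermi-Dirac binding probability 1 / (1 + exp(energy - mu)).

    Accepts scalars or arrays.  Strictly decreasing in energy; saturates
    to exactly 1.0 / 0.0 at the infinite-energy limits without overflow.
    """
    e = np.asarray(energy, dtype=float)
    out = expit(-(e - mu))
    return float(out) if np.isscalar(energy) or e.ndim == 0 else out


def index_to_sequence(index: int, width: int) -> str:
    """Decode a base-4 landscape index (A=0, C=1, G=2, T=3) to a string."""
    letters = []
    for j in range(width):
        letters.append(BASES[(index >> (2 * (width - 1 - j))) & 3])
    return "".join(letters)


def sequence_to_index(sequence: str) -> int:
    idx = 0
    for ch in sequence:
        b = BASES.find(ch)
        if b < 0:
            raise InvalidSequenceError(f"invalid base {ch!r}")
        idx = (idx << 2) | b
    return idx


def _all_digits(width: int) -> np.ndarray:
    codes = np.arange(4 ** width)
    shifts = 2 * np.arange(width - 1, -1, -1)
    return (codes[:, None] >> shifts[None, :]) & 3


def landscape_energies(matrix: EnergyMatrix) -> np.ndarray:
    """Vector of additive energies for all 4^L sequences, in index order."""
    L = matrix.width
    if L > MAX_WIDTH:
        raise ValueError(
            f"width {L} exceeds the enumeration guard of {MAX_WIDTH}"
        )
    if matrix.undetermined:
        raise ValueError(
            f"matrix {matrix.model_id!r} has undetermined entries; cannot "
            "enumerate its landscape"
        )
    digits = _all_digits(L)
    return matrix.energies[np.arange(L)[None, :], digits].sum(axis=1)


def reverse_complement_index(width: int) -> np.ndarray:
    """Permutation mapping each landscape index to its reverse complement."""
    digits = _all_digits(width)
    rc_digits = 3 - digits[:, ::-1]
    shifts = 2 * np.arange(width - 1, -1, -1)
    return (rc_digits << shifts[None, :]).sum(axis=1)


@dataclasses.dataclass(frozen=True)
class SampleConfig:
    """Conditions of a site-sampling run.

    Defaults are the study conditions: 500 sites drawn with replacement at
    chemical potential mu = -0.5.
    """

    mu: float = -0.5
    n_sites: int = 500
    seed: int = 0
    replacement: bool = True

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if not np.isfinite(self.mu):
            raise ValueError("mu must be finite")


@dataclasses.dataclass(eq=False)
class Landscape:
    """All 4^L sequences of a model with energies and sampling probabilities."""

    matrix: EnergyMatrix
    mu: float
    energies: np.ndarray      # (4^L,) binding energies, kT
    occupancies: np.ndarray   # (4^L,) theta(E_i)
    probs: np.ndarray         # (4^L,) pi_i, sums to 1

    @property
    def width(self) -> int:
        return self.matrix.width

    @property
    def n_sequences(self) -> int:
        return self.energies.shape[0]

    def sequence(self, index: int) -> str:
        return index_to_sequence(index, self.width)

    @property
    def consensus_index(self) -> int:
        return int(np.argmax(self.probs))

    def marginals(self) -> np.ndarray:
        """(L, 4) per-position base probabilities of the true motif.

        These are the pi-weighted base frequencies: the expected column
        frequencies of an infinitely large site sample.
        """
        digits = _all_digits(self.width)
        marg = np.zeros((self.width, 4))
        for j in range(self.width):
            marg[j] = np.bincount(digits[:, j], weights=self.probs, minlength=4)
        return marg

    def information(self, background=(0.25, 0.25, 0.25, 0.25)) -> float:
        """Information content (bits) of the true motif's marginals."""
        f = self.marginals()
        bg = np.asarray(background)
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(f > 0, f * np.log2(f / bg), 0.0)
        return float(terms.sum())


def enumerate_landscape(matrix: EnergyMatrix, mu: float | None = None) -> Landscape:
    """Enumerate all 4^L sequences with energies, occupancies and pi.

    Refuses widths above :data:`MAX_WIDTH`.  The result satisfies
    sum(pi) == 1 to within 1e-12 and pi is strictly decreasing in energy.
    """
    if mu is None:
        mu = matrix.mu_default
    E = landscape_energies(matrix)
    occ = occupancy(E, mu)
    probs = occ / occ.sum()
    return Landscape(matrix, float(mu), E, occ, probs)


@dataclasses.dataclass(eq=False)
class SiteSample:
    """A seeded random sample of binding sites with their true energies."""

    model_id: str
    config: SampleConfig
    sites: tuple[str, ...]
    energies: np.ndarray
    provenance: dict = dataclasses.field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.sites)

    @property
    def width(self) -> int:
        return len(self.sites[0])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SiteSample):
            return NotImplemented
        return (
            self.model_id == other.model_id
            and self.config == other.config
            and self.sites == other.sites
            and np.array_equal(self.energies, other.energies)
        )


def sample_sites(landscape: Landscape, config: SampleConfig) -> SiteSample:
    """Draw ``config.n_sites`` sites from pi with a seeded generator.

    Identical (landscape, config) always yields an identical sample.
    """
    rng = np.random.default_rng(config.seed)
    if not config.replacement:
        supported = int(np.count_nonzero(landscape.probs > 1e-15))
        if config.n_sites > supported:
            raise ValueError(
                f"cannot draw {config.n_sites} sites without replacement: "
                f"only {supported} sequences have non-negligible probability"
            )
    idx = rng.choice(
        landscape.n_sequences,
        size=config.n_sites,
        replace=config.replacement,
        p=landscape.probs,
    )
    sites = tuple(landscape.sequence(int(i)) for i in idx)
    energies = landscape.energies[idx].copy()
    provenance = {
        "generator": f"symmotif {__version__}",
        "model_id": landscape.matrix.model_id,
        "mu": landscape.mu,
        "seed": config.seed,
    }
    return SiteSample(
        landscape.matrix.model_id, config, sites, energies, provenance
    )


def simulate(
    matrix: EnergyMatrix, config: SampleConfig | None = None, **kwargs
) -> SiteSample:
    """Convenience wrapper: enumerate the landscape and sample from it."""
    if config is None:
        config = SampleConfig(**kwargs)
    return sample_sites(enumerate_landscape(matrix, config.mu), config)


# -- sample file dialect ----------------------------------------------------
#
# TSV with '#'-prefixed "key: value" metadata lines, a "site\tenergy"
# header, then one site per row.  This emulates the layout of a published
# selected-sites-and-energies supplementary table while remaining trivially
# parseable; `read_sample` also ingests such third-party files through the
# column-mapping arguments.


def write_sample(sample: SiteSample, path) -> None:
    lines = [
        f"# model_id: {sample.model_id}",
        f"# mu: {sample.config.mu!r}",
        f"# n_sites: {sample.config.n_sites}",
        f"# seed: {sample.config.seed}",
        f"# generator: {sample.provenance.get('generator', 'unknown')}",
        "site\tenergy",
    ]
    for s, e in zip(sample.sites, sample.energies):
        lines.append(f"{s}\t{float(e)!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_sample(
    path,
    *,
    sep: str = "\t",
    site_col: int = 0,
    energy_col: int = 1,
    comment: str = "#",
    matrix: EnergyMatrix | None = None,
) -> SiteSample:
    """Read a site/energy table; raises :class:`SampleFileError` with the
    offending line number on malformed input.

    ``site_col``/``energy_col``/``sep`` allow ingesting third-party
    supplementary files whose columns are laid out differently.  When
    ``matrix`` is given, every stored energy is checked against
    :func:`site_energy` for that matrix.
    """
    meta: dict[str, str] = {}
    sites: list[str] = []
    energies: list[float] = []
    width = None
    text = Path(path).read_text()
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith(comment):
            body = line.lstrip(comment).strip()
            if ":" in body:
                key, _, val = body.partition(":")
                meta[key.strip()] = val.strip()
            continue
        fields = line.split(sep)
        if max(site_col, energy_col) >= len(fields):
            raise SampleFileError(
                f"line {lineno}: expected at least "
                f"{max(site_col, energy_col) + 1} columns, got {len(fields)}"
            )
        site = fields[site_col].strip().upper()
        raw_energy = fields[energy_col].strip()
        try:
            energy = float(raw_energy)
        except ValueError:
            if not sites and site.isalpha():
                continue  # header row
            raise SampleFileError(
                f"line {lineno}: cannot parse energy {raw_energy!r}"
            ) from None
        if any(ch not in "ACGT" for ch in site):
            raise SampleFileError(
                f"line {lineno}: site {site!r} contains non-ACGT characters"
            )
        if width is None:
            width = len(site)
        elif len(site) != width:
            raise SampleFileError(
                f"line {lineno}: site length {len(site)} differs from "
                f"{width} seen earlier"
            )
        sites.append(site)
        energies.append(energy)
    if not sites:
        raise SampleFileError(f"{path}: no site records found")
    if matrix is not None:
        for i, (s, e) in enumerate(zip(sites, energies), start=1):
            expected = site_energy(matrix, s)
            if abs(expected - e) > 1e-6:
                raise SampleFileError(
                    f"record {i}: stored energy {e} does not match matrix "
                    f"energy {expected}"
                )
    config = SampleConfig(
        mu=float(meta.get("mu", -0.5)),
        n_sites=len(sites),
        seed=int(meta.get("seed", 0)),
    )
    model_id = meta.get("model_id", Path(path).stem)
    provenance = {"source": str(path), **meta}
    return SiteSample(model_id, config, tuple(sites), np.array(energies), provenance)
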