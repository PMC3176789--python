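"""Model accuracy over the full sequence landscape.

A discovered motif is useful insofar as it ranks and weighs *all* possible
sites the way the true energy model does.  Accuracy is therefore measured
landscape-wide: convert the motif's frequencies to an additive energy
matrix, compute the log total binding probability (both strands) of every
possible L-mer under both the true and the fitted matrix at the sampling
chemical potential, and report R^2, the squared Pearson correlation of the
two vectors.

The frequency-to-energy conversion inverts the sampling model in the
low-occupancy regime where frequencies are proportional to Boltzmann
factors:  epsilon(b, j) = ln( f_max(j) / f(b, j) ), with a pseudocount so
unobserved bases get a large finite penalty rather than an infinite one.
"""
from __future__ import annotations

import dataclasses
import logging

import numpy as np

from .energy_models import EnergyMatrix, reverse_complement, site_energy
from .motif_discovery import (
    DiscoveryConfig,
    MotifModel,
    discover_asymmetric,
    discover_fixed,
    discover_symmetric,
    information_content,
)
from .significance import evalue_report, select_model
from .synthetic_sites import (
    SiteSample,
    enumerate_landscape,
    landscape_energies,
    occupancy,
    reverse_complement_index,
)

logger = logging.getLogger(__name__)

COMBINE_RULES = ("sum", "max")


@dataclasses.dataclass(eq=False)
class LandscapeEvaluation:
    """True vs predicted log binding probability over all 4^L sequences."""

    model_id: str
    mode: str
    combine_rule: str
    true_log_occupancy: np.ndarray
    predicted_log_occupancy: np.ndarray
    r_squared: float


def pwm_to_energy(
    model: MotifModel,
    pseudocount: float = 0.5,
    *,
    model_id: str | None = None,
    mu: float = -0.5,
) -> EnergyMatrix:
    """Convert motif frequencies to an additive energy matrix (kT).

    epsilon(b, j) = ln(f_max(j) / f(b, j)) after pseudocounting, so the
    preferred base of each column sits at exactly 0.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be nonnegative")
    if pseudocount == 0 and np.any(model.counts == 0):
        raise ValueError(
            "zero counts present; a positive pseudocount is required to "
            "convert frequencies to finite energies"
        )
    f = model.frequencies(pseudocount)
    eps = np.log(f.max(axis=1, keepdims=True) / f)
    return EnergyMatrix(
        model_id or f"{model.mode}-pwm", eps, mu
    )


def log_occupancy_both_strands(
    matrix: EnergyMatrix,
    sequence: str,
    mu: float | None = None,
    combine: str = "sum",
) -> float:
    """ln of the binding probability of a site counting both orientations.

    ``combine="sum"`` (default) uses theta(E_fwd) + theta(E_rev);
    ``combine="max"`` uses the larger of the two terms.
    """
    if combine not in COMBINE_RULES:
        raise ValueError(f"combine must be one of {COMBINE_RULES}")
    if mu is None:
        mu = matrix.mu_default
    of = occupancy(site_energy(matrix, sequence), mu)
    orc = occupancy(site_energy(matrix, reverse_complement(sequence)), mu)
    return float(np.log(of + orc if combine == "sum" else max(of, orc)))


def _log_occupancy_vector(matrix: EnergyMatrix, mu: float, combine: str) -> np.ndarray:
    E = landscape_energies(matrix)
    rc = reverse_complement_index(matrix.width)
    of = occupancy(E, mu)
    orc = of[rc]
    return np.log(of + orc if combine == "sum" else np.maximum(of, orc))


def r_squared(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation coefficient."""
    return float(np.corrcoef(x, y)[0, 1] ** 2)


def evaluate_matrices(
    true_matrix: EnergyMatrix,
    predicted_matrix: EnergyMatrix,
    mu: float = -0.5,
    combine: str = "sum",
) -> tuple[np.ndarray, np.ndarray, float]:
    """Landscape log-occupancy vectors for two matrices and their R^2."""
    if true_matrix.width != predicted_matrix.width:
        raise ValueError(
            f"width mismatch: true {true_matrix.width} vs predicted "
            f"{predicted_matrix.width}"
        )
    t = _log_occupancy_vector(true_matrix, mu, combine)
    p = _log_occupancy_vector(predicted_matrix, mu, combine)
    return t, p, r_squared(t, p)


def evaluate_model(
    true_matrix: EnergyMatrix,
    model: MotifModel,
    mu: float = -0.5,
    combine: str = "sum",
    pseudocount: float = 0.5,
) -> LandscapeEvaluation:
    """R^2 of a discovered motif against the generating energy model."""
    predicted = pwm_to_energy(model, pseudocount, mu=mu)
    t, p, r2 = evaluate_matrices(true_matrix, predicted, mu, combine)
    return LandscapeEvaluation(
        true_matrix.model_id, model.mode, combine, t, p, r2
    )


# -- study tables -----------------------------------------------------------

_T1_ROWS = [
    ("Info Content", "True"),
    ("Info Content", "Asym"),
    ("Info Content", "Sym"),
    ("-ln(E-value)", "Asym"),
    ("-ln(E-value)", "Sym"),
]
_T2_ROWS = ["Control", "Asym", "Sym"]


@dataclasses.dataclass(eq=False)
class StudyTables:
    """Two-block study report: information/-lnE and landscape R^2.

    ``table1`` rows: true/asym/sym information content and the two modes'
    -ln(E-value); ``table2`` rows: Control/Asym/Sym R^2; columns are model
    ids.  ``verdicts`` maps model id to the E-value-selected mode, and
    ``details`` keeps every intermediate object for inspection.
    """

    table1: "pandas.DataFrame"
    table2: "pandas.DataFrame"
    verdicts: dict
    details: dict

    def to_text(self) -> str:
        lines = ["Information content and -ln(E-value) for predicted matrices"]
        lines.append(self.table1.to_string(float_format=lambda v: f"{v:.1f}"))
        lines.append("")
        lines.append("R^2 between predicted energies and true energies")
        lines.append(self.table2.to_string(float_format=lambda v: f"{v:.2f}"))
        lines.append("")
        lines.append("E-value winner per dataset:")
        for mid, verdict in self.verdicts.items():
            lines.append(f"  {mid}: {verdict}")
        return "\n".join(lines) + "\n"


def replicate_tables(
    samples: dict[str, SiteSample],
    true_matrices: dict[str, EnergyMatrix],
    *,
    discovery: DiscoveryConfig | None = None,
    mu: float = -0.5,
    combine: str = "sum",
    bin_width: float = 0.005,
    pseudocount: float = 0.5,
) -> StudyTables:
    """Run discovery, significance and evaluation for every dataset.

    ``samples`` maps model id to its site sample; a model id present in
    ``true_matrices`` but absent from ``samples`` appears as an absent
    (NaN) column.  Empty input yields empty tables.
    """
    import pandas as pd

    discovery = discovery or DiscoveryConfig()
    model_ids = list(true_matrices)
    t1 = pd.DataFrame(
        np.nan, index=pd.MultiIndex.from_tuples(_T1_ROWS), columns=model_ids
    )
    t2 = pd.DataFrame(np.nan, index=_T2_ROWS, columns=model_ids)
    verdicts: dict = {}
    details: dict = {}
    for mid in model_ids:
        truth = true_matrices[mid]
        if mid not in samples:
            logger.warning("no sample for model %s; column left absent", mid)
            verdicts[mid] = "absent"
            continue
        sample = samples[mid]
        landscape = enumerate_landscape(truth, mu)
        fixed = discover_fixed(sample, discovery)
        asym = discover_asymmetric(sample, discovery)
        sym = discover_symmetric(sample, discovery)
        rep_asym = evalue_report(asym, bin_width=bin_width)
        rep_sym = evalue_report(sym, bin_width=bin_width)
        choice = select_model(rep_asym, rep_sym)
        evals = {
            "Control": evaluate_model(truth, fixed, mu, combine, pseudocount),
            "Asym": evaluate_model(truth, asym, mu, combine, pseudocount),
            "Sym": evaluate_model(truth, sym, mu, combine, pseudocount),
        }
        t1.loc[("Info Content", "True"), mid] = landscape.information(
            discovery.background
        )
        t1.loc[("Info Content", "Asym"), mid] = rep_asym.information_bits
        t1.loc[("Info Content", "Sym"), mid] = rep_sym.information_bits
        t1.loc[("-ln(E-value)", "Asym"), mid] = rep_asym.minus_ln_evalue
        t1.loc[("-ln(E-value)", "Sym"), mid] = rep_sym.minus_ln_evalue
        for row, ev in evals.items():
            t2.loc[row, mid] = ev.r_squared
        verdicts[mid] = choice.verdict
        details[mid] = {
            "sample": sample,
            "models": {"fixed": fixed, "asymmetric": asym, "symmetric": sym},
            "reports": {"asymmetric": rep_asym, "symmetric": rep_sym},
            "selection": choice,
            "evaluations": evals,
        }
    return StudyTables(t1, t2, verdicts, details)
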