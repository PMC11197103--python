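"""Conformer-ensemble statistics: Boltzmann populations with analytic
uncertainty propagation, ensemble J-averaging, staggered-rotamer
bookkeeping, and the J-vs-%antiperiplanar correlation.

Populations follow the Boltzmann distribution over relative free energies,

    p_k = g_k exp(−E_k/RT) / Z,     Z = Σ_n g_n exp(−E_n/RT),

with g_k an explicit degeneracy multiplier.  Treating all energies as
relative to E_k and assigning every other energy the same standard
deviation σ_E, first-order propagation of the energy uncertainty gives

    ∂p_k/∂E_n = p_k p_n / RT            (n ≠ k)
    σ_{p_k}   = (σ_E/RT) · p_k · sqrt(Σ_{n≠k} p_n²)
              ≤ (σ_E/RT) · p_k · (1 − p_k)          (upper bound),

the bound following from the triangle inequality on the inner sum; it is
convenient because it involves no sum over the other probabilities.  The
default σ_E of 0.42 kJ/mol is the energy-difference error estimated by
comparing dissimilar high-level electronic-structure methods on the same
torsional scan; 1.1 kJ/mol is the corresponding worst-case figure.

Dihedral labels use the staggered alphabet ``a`` (anti, ≈180°), ``g``
(gauche, ≈+60°) and ``g-`` (≈−60°); a conformer label is the concatenated
per-dihedral string, e.g. ``"ag-"`` for two dihedrals or ``"agg-a"`` for
four.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "R_J_PER_MOL_K",
    "DEFAULT_T_K",
    "DEFAULT_SIGMA_E_KJ",
    "TOKENS",
    "ConformerEnsemble",
    "PopulationResult",
    "parse_label",
    "boltzmann_populations",
    "population_uncertainty",
    "ensemble_average_J",
    "enumerate_staggered",
    "condense_grid",
    "percent_antiperiplanar",
    "correlate_J_app",
    "classify_dihedral",
    "read_conformer_table",
    "write_conformer_table",
]

R_J_PER_MOL_K = 8.31446
DEFAULT_T_K = 298.0
#: optimistic (method-comparison) and worst-case energy standard deviations
DEFAULT_SIGMA_E_KJ = 0.42
WORST_CASE_SIGMA_E_KJ = 1.1

TOKENS = ("a", "g", "g-")
_TOKEN_RE = re.compile(r"g-|g|a")


def parse_label(label: str) -> tuple[str, ...]:
    """Split a conformer label into per-dihedral tokens (greedy: ``g``
    followed by ``-`` is one token)."""
    toks = _TOKEN_RE.findall(label)
    if "".join(toks) != label:
        raise ValueError(f"invalid conformer label {label!r}")
    return tuple(toks)


def classify_dihedral(theta_deg: float) -> str:
    """Staggered-well token of a dihedral angle: ``a`` within ±60° of 180°,
    ``g``/``g-`` within ±60° of +60°/−60°."""
    t = (theta_deg + 180.0) % 360.0 - 180.0  # wrap to (-180, 180]
    if abs(t) > 120.0:
        return "a"
    return "g" if t > 0 else "g-"


def is_antiperiplanar(theta_deg: float, window_deg: float = 30.0) -> bool:
    """True when the dihedral lies within ±window of 180°."""
    t = (theta_deg + 180.0) % 360.0 - 180.0
    return abs(t) > 180.0 - window_deg


# ---------------------------------------------------------------------- #

@dataclass
class ConformerEnsemble:
    """Labelled conformers with relative free energies and optional
    per-conformer properties.

    Energies are stored relative to the most stable conformer (the minimum
    is shifted to zero on construction — a pure gauge choice that leaves
    populations untouched).
    """

    labels: list[str]
    energies_kj: np.ndarray
    degeneracy: np.ndarray | None = None
    dipole_debye: np.ndarray | None = None
    j_table: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.energies_kj = np.asarray(self.energies_kj, dtype=float)
        n = len(self.labels)
        if self.energies_kj.shape != (n,):
            raise ValueError("energies_kj length does not match labels")
        if self.degeneracy is None:
            self.degeneracy = np.ones(n, dtype=int)
        self.degeneracy = np.asarray(self.degeneracy, dtype=int)
        if np.any(self.degeneracy < 1):
            raise ValueError("degeneracies must be >= 1")
        for lab in self.labels:
            parse_label(lab)
        widths = {len(parse_label(lab)) for lab in self.labels}
        if len(widths) > 1:
            raise ValueError("all labels must have the same dihedral count")
        self.energies_kj = self.energies_kj - self.energies_kj.min()
        for key, vals in self.j_table.items():
            vals = np.asarray(vals, dtype=float)
            if vals.shape != (n,):
                raise ValueError(
                    f"j_table[{key!r}] length does not match conformer count"
                )
            self.j_table[key] = vals

    @property
    def n_conformers(self) -> int:
        return len(self.labels)

    @property
    def n_dihedrals(self) -> int:
        return len(parse_label(self.labels[0]))


@dataclass
class PopulationResult:
    """Boltzmann populations with propagated uncertainties."""

    labels: list[str]
    p: np.ndarray
    sigma_p: np.ndarray
    sigma_p_bound: np.ndarray
    T: float
    sigma_E: float

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "label": self.labels,
            "population": self.p,
            "sigma": self.sigma_p,
            "sigma_upper_bound": self.sigma_p_bound,
        })


def _weights(ensemble: ConformerEnsemble, T: float) -> np.ndarray:
    if not T > 0:
        raise ValueError("temperature must be > 0")
    rt = R_J_PER_MOL_K * T / 1000.0  # kJ/mol
    return ensemble.degeneracy * np.exp(-ensemble.energies_kj / rt)


def boltzmann_populations(ensemble: ConformerEnsemble,
                          T: float = DEFAULT_T_K) -> PopulationResult:
    """Degeneracy-weighted Boltzmann populations at temperature T."""
    w = _weights(ensemble, T)
    p = w / w.sum()
    z = np.zeros_like(p)
    return PopulationResult(list(ensemble.labels), p, z, z.copy(), T, 0.0)


def population_uncertainty(ensemble: ConformerEnsemble,
                           T: float = DEFAULT_T_K,
                           sigma_E: float = DEFAULT_SIGMA_E_KJ
                           ) -> PopulationResult:
    """First-order propagation of a common energy standard deviation σ_E
    (kJ/mol) into population standard deviations, with the closed-form
    upper bound (see module docstring for the algebra)."""
    if sigma_E < 0:
        raise ValueError("sigma_E must be >= 0")
    w = _weights(ensemble, T)
    p = w / w.sum()
    rt = R_J_PER_MOL_K * T / 1000.0
    s = sigma_E / rt
    sumsq = np.array([np.sum(p ** 2) - p[k] ** 2 for k in range(len(p))])
    sigma_p = s * p * np.sqrt(sumsq)
    bound = s * p * (1.0 - p)
    return PopulationResult(list(ensemble.labels), p, sigma_p, bound,
                            T, sigma_E)


def ensemble_average_J(ensemble: ConformerEnsemble, T: float,
                       pair: str) -> float:
    """Boltzmann- and degeneracy-weighted ensemble average of the
    per-conformer coupling for the given atom pair (Hz)."""
    if pair not in ensemble.j_table:
        raise KeyError(f"no J values for pair {pair!r}")
    w = _weights(ensemble, T)
    return float(np.sum(ensemble.j_table[pair] * w) / w.sum())


# ---------------------------------------------------------------------- #

def enumerate_staggered(n_dihedrals: int) -> ConformerEnsemble:
    """Skeleton ensemble of all 3ⁿ staggered conformations (zero energies,
    unit degeneracy): 9 conformers for two dihedrals, 81 for four."""
    if n_dihedrals < 1:
        raise ValueError("n_dihedrals must be >= 1")
    labels = ["".join(t) for t in
              itertools.product(TOKENS, repeat=n_dihedrals)]
    return ConformerEnsemble(labels, np.zeros(len(labels)))


def condense_grid(populations: pd.Series | dict, axis: str = "inner"
                  ) -> pd.DataFrame:
    """Condense a 4-dihedral population grid to the 3×3 marginal over the
    selected dihedral pair.

    ``axis="inner"`` keeps the two central dihedrals (positions 2 and 3 of
    the label), summing over the outer pair; ``axis="outer"`` keeps the
    first and last positions.  Each cell is then the sum of the populations
    of the nine conformations sharing that pair; the grand total is
    preserved.
    """
    if isinstance(populations, dict):
        populations = pd.Series(populations)
    if axis not in ("inner", "outer"):
        raise ValueError("axis must be 'inner' or 'outer'")
    grid = pd.DataFrame(0.0, index=list(TOKENS), columns=list(TOKENS))
    for label, pop in populations.items():
        toks = parse_label(label)
        if len(toks) != 4:
            raise ValueError(
                f"malformed grid: label {label!r} does not have 4 dihedrals"
            )
        i, j = (toks[1], toks[2]) if axis == "inner" else (toks[0], toks[3])
        grid.loc[i, j] += pop
    return grid


def percent_antiperiplanar(ensemble: ConformerEnsemble,
                           pair_geometry: dict[str, bool],
                           T: float = DEFAULT_T_K) -> float:
    """Percentage of the population in conformers where the given atom pair
    is antiperiplanar, per the supplied conformer → app classification."""
    missing = [lab for lab in ensemble.labels if lab not in pair_geometry]
    if missing:
        raise KeyError(
            f"pair_geometry does not cover conformers {missing[:5]}"
        )
    pops = boltzmann_populations(ensemble, T).p
    sel = np.array([bool(pair_geometry[lab]) for lab in ensemble.labels])
    return float(100.0 * pops[sel].sum())


def correlate_J_app(j_values, app_percentages) -> tuple[float, float, float]:
    """Ordinary least-squares line of coupling (Hz) against %app.

    Returns ``(slope, intercept, r_squared)``; requires at least three
    points and a non-constant predictor.
    """
    x = np.asarray(app_percentages, dtype=float)
    y = np.asarray(j_values, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("J values and %app must be equal-length 1-D lists")
    if len(x) < 3:
        raise ValueError("at least three points are required")
    if np.ptp(x) == 0:
        raise ValueError("degenerate (constant) predictor")
    fit = stats.linregress(x, y)
    return float(fit.slope), float(fit.intercept), float(fit.rvalue ** 2)


# ---------------------------------------------------------------------- #
# delimited-text round trip
# ---------------------------------------------------------------------- #

def write_conformer_table(ensemble: ConformerEnsemble,
                          path: str | Path) -> None:
    """Write the ensemble as a delimited table (label, energy_kJmol,
    degeneracy, dipole_D, J_<pair> columns)."""
    data = {"label": ensemble.labels,
            "energy_kJmol": ensemble.energies_kj,
            "degeneracy": ensemble.degeneracy}
    if ensemble.dipole_debye is not None:
        data["dipole_D"] = ensemble.dipole_debye
    for pair, vals in ensemble.j_table.items():
        data[f"J_{pair}"] = vals
    pd.DataFrame(data).to_csv(path, index=False)


def read_conformer_table(path: str | Path) -> ConformerEnsemble:
    df = pd.read_csv(path)
    need = {"label", "energy_kJmol"}
    if not need.issubset(df.columns):
        raise ValueError(f"conformer table must have columns {sorted(need)}")
    j_table = {
        col[2:]: df[col].to_numpy(dtype=float)
        for col in df.columns if col.startswith("J_")
    }
    return ConformerEnsemble(
        labels=[str(x) for x in df["label"]],
        energies_kj=df["energy_kJmol"].to_numpy(dtype=float),
        degeneracy=df["degeneracy"].to_numpy(dtype=int)
        if "degeneracy" in df.columns else None,
        dipole_debye=df["dipole_D"].to_numpy(dtype=float)
        if "dipole_D" in df.columns else None,
        j_table=j_table,
    )
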