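"""Sequential two-site and 1:1 binding models for chlorin-protein titrations.

The sequential model describes two ligands binding one protein dimer P
with macroscopic stepwise dissociation constants

    P  + L <-> PL    K_D1 = [P][L]/[PL]
    PL + L <-> PL2   K_D2 = [PL][L]/[PL2]

Free-ligand concentration is solved by monotone bracketing (Brent), and
all other species follow from mass action.  Observed signals are linear
in species concentrations:

* CD mode:          y = s_PL [PL] + s_PL2 [PL2]
* absorbance mode:  y = l (eps_free [L] + eps_PL [PL] + 2 eps_PL2 [PL2])

where extinction coefficients are per bound chromophore, so the doubly
loaded species contributes twice its concentration.  Fitting exploits
that linearity: the nonlinear search runs over (log10 K_D1, log10 K_D2)
only, with the signal coefficients profiled out by linear least squares
at each step (variable projection).  In absorbance mode eps_free is held
fixed -- it is measurable from a ligand-only dilution series.

Fluorescence-lifetime energy transfer utilities (amplitude-weighted mean
lifetime, E = 1 - tau_DA / tau_D) live here too.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, least_squares

__all__ = [
    "SequentialBindingModel",
    "TitrationExperiment",
    "FitResult",
    "solve_species",
    "simulate_titration",
    "fit_sequential",
    "fit_one_site",
    "fret_efficiency",
    "average_lifetime",
]


@dataclass
class SequentialBindingModel:
    """Stepwise two-site binding constants plus per-species signal coefficients.

    ``signal_mode`` selects the observable: "cd" uses (s_pl, s_pl2) per
    molar species; "absorbance" uses per-chromophore molar extinctions
    (eps_free, eps_pl, eps_pl2, M^-1 cm^-1).
    """

    kd1: float
    kd2: float
    signal_mode: str = "cd"
    s_pl: float = 0.0
    s_pl2: float = 0.0
    eps_free: float = 0.0
    eps_pl: float = 0.0
    eps_pl2: float = 0.0

    def __post_init__(self) -> None:
        if self.kd1 <= 0 or self.kd2 <= 0:
            raise ValueError("dissociation constants must be positive")
        if self.signal_mode not in {"cd", "absorbance"}:
            raise ValueError(f"unknown signal mode {self.signal_mode!r}")

    def signal(self, species: dict[str, float], path_length: float = 1.0) -> float:
        if self.signal_mode == "cd":
            return self.s_pl * species["PL"] + self.s_pl2 * species["PL2"]
        return path_length * (
            self.eps_free * species["L"]
            + self.eps_pl * species["PL"]
            + 2.0 * self.eps_pl2 * species["PL2"]
        )


def solve_species(
    model: SequentialBindingModel, protein_total: float, ligand_total: float
) -> dict[str, float]:
    """Equilibrium concentrations {P, PL, PL2, L} by bracketing on free ligand.

    The total-ligand function L + PL + 2 PL2 is strictly increasing in free
    L, so the root is bracketed in [0, L_T] and found by Brent's method.
    """
    if protein_total < 0 or ligand_total < 0:
        raise ValueError("totals must be non-negative")
    kd1, kd2 = model.kd1, model.kd2

    def species_at(L: float) -> dict[str, float]:
        denom = 1.0 + L / kd1 + L * L / (kd1 * kd2)
        P = protein_total / denom
        PL = P * L / kd1
        PL2 = PL * L / kd2
        return {"P": P, "PL": PL, "PL2": PL2, "L": L}

    if ligand_total == 0.0:
        return species_at(0.0)

    def excess(L: float) -> float:
        sp = species_at(L)
        return L + sp["PL"] + 2.0 * sp["PL2"] - ligand_total

    lo, hi = 0.0, ligand_total
    if excess(hi) < 0:  # numerically impossible: bound ligand cannot exceed total
        raise RuntimeError("species solver failed to bracket the root")
    L = brentq(excess, lo, hi, xtol=1e-300, rtol=8.9e-16, maxiter=200)
    sp = species_at(L)
    # verify conservation to the promised tolerance
    scale_l = max(ligand_total, 1e-300)
    resid_l = abs(sp["L"] + sp["PL"] + 2 * sp["PL2"] - ligand_total) / scale_l
    if protein_total > 0:
        resid_p = abs(sp["P"] + sp["PL"] + sp["PL2"] - protein_total) / protein_total
    else:
        resid_p = 0.0
    if resid_l > 1e-10 or resid_p > 1e-10:
        raise RuntimeError(
            f"species solver did not converge (residuals {resid_l:.2e}, {resid_p:.2e})"
        )
    return sp


@dataclass
class TitrationExperiment:
    """One titration: fixed protein (dimer units), increasing ligand, one signal."""

    protein_total: float
    ligand_totals: np.ndarray
    observed: np.ndarray
    signal_mode: str = "cd"
    path_length: float = 1.0
    noise_sd: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        self.ligand_totals = np.asarray(self.ligand_totals, dtype=float)
        self.observed = np.asarray(self.observed, dtype=float)
        if np.any(self.ligand_totals < 0):
            raise ValueError("ligand totals must be non-negative")
        if np.any(np.diff(self.ligand_totals) <= 0):
            raise ValueError("ligand totals must be strictly increasing")
        if len(self.observed) != len(self.ligand_totals):
            raise ValueError("observed length mismatch")


def model_curve(
    model: SequentialBindingModel,
    protein_total: float,
    ligand_totals: np.ndarray,
    path_length: float = 1.0,
) -> np.ndarray:
    return np.array(
        [
            model.signal(solve_species(model, protein_total, lt), path_length)
            for lt in np.asarray(ligand_totals, dtype=float)
        ]
    )


def simulate_titration(
    model: SequentialBindingModel,
    protein_total: float,
    ligand_totals: np.ndarray,
    noise_sd: float = 0.0,
    seed: int | None = None,
    path_length: float = 1.0,
) -> TitrationExperiment:
    """Synthetic titration: model curve plus i.i.d. Gaussian noise (seeded)."""
    curve = model_curve(model, protein_total, ligand_totals, path_length)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        curve = curve + rng.normal(0.0, noise_sd, size=len(curve))
    return TitrationExperiment(
        protein_total=protein_total,
        ligand_totals=np.asarray(ligand_totals, dtype=float),
        observed=curve,
        signal_mode=model.signal_mode,
        path_length=path_length,
        noise_sd=noise_sd,
        seed=seed,
    )


@dataclass
class FitResult:
    params: dict[str, float]
    residual_norm: float
    converged: bool
    model: SequentialBindingModel | None = None

    def __post_init__(self) -> None:
        if self.residual_norm < 0:
            raise ValueError("residual norm must be non-negative")


def _species_table(kd1, kd2, protein_total, ligand_totals):
    m = SequentialBindingModel(kd1, kd2)
    rows = [solve_species(m, protein_total, lt) for lt in ligand_totals]
    return (
        np.array([r["L"] for r in rows]),
        np.array([r["PL"] for r in rows]),
        np.array([r["PL2"] for r in rows]),
    )


def fit_sequential(
    exp: TitrationExperiment,
    initial_guess: tuple[float, float] | None = None,
    eps_free: float | None = None,
    n_starts: int = 5,
) -> FitResult:
    """Nonlinear least squares for the sequential model.

    Searches over (log10 K_D1, log10 K_D2); species signal coefficients are
    profiled out linearly at each step.  In absorbance mode ``eps_free``
    must be supplied and is held fixed.  Multi-start over a log-spaced
    K_D grid guards against local minima; ``initial_guess`` (kd1, kd2)
    adds one more start.
    """
    if len(exp.ligand_totals) < 6:
        raise ValueError("need at least 6 titration points")
    if exp.signal_mode == "absorbance" and eps_free is None:
        raise ValueError("absorbance fits require the free-ligand extinction eps_free")
    y = exp.observed
    lt = exp.ligand_totals
    pt = exp.protein_total
    pl_len = exp.path_length

    def design(kd1, kd2):
        L, PL, PL2 = _species_table(kd1, kd2, pt, lt)
        if exp.signal_mode == "cd":
            A = np.column_stack([PL, PL2])
            target = y
        else:
            A = np.column_stack([pl_len * PL, 2.0 * pl_len * PL2])
            target = y - pl_len * eps_free * L
        return A, target

    def residuals(logkd):
        kd1, kd2 = 10.0 ** logkd
        A, target = design(kd1, kd2)
        coef, *_ = np.linalg.lstsq(A, target, rcond=None)
        return A @ coef - target

    span = np.log10(max(lt.max(), 1e-12))
    starts = [
        (span - 2.0, span - 0.5),
        (span - 1.0, span - 1.0),
        (span - 3.0, span - 1.5),
        (span - 0.5, span - 2.5),
        (span - 2.5, span + 0.5),
    ][: max(1, n_starts)]
    if initial_guess is not None:
        starts.append((np.log10(initial_guess[0]), np.log10(initial_guess[1])))

    best = None
    for s in starts:
        try:
            sol = least_squares(residuals, x0=np.array(s), method="trf", xtol=1e-14)
        except (RuntimeError, ValueError):
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        return FitResult({}, float("inf"), converged=False)

    kd1, kd2 = 10.0 ** best.x
    A, target = design(kd1, kd2)
    coef, *_ = np.linalg.lstsq(A, target, rcond=None)
    singular = np.linalg.matrix_rank(A) < A.shape[1]
    if exp.signal_mode == "cd":
        params = {"kd1": kd1, "kd2": kd2, "s_pl": coef[0], "s_pl2": coef[1]}
        model = SequentialBindingModel(kd1, kd2, "cd", s_pl=coef[0], s_pl2=coef[1])
    else:
        params = {
            "kd1": kd1,
            "kd2": kd2,
            "eps_free": eps_free,
            "eps_pl": coef[0],
            "eps_pl2": coef[1],
        }
        model = SequentialBindingModel(
            kd1, kd2, "absorbance", eps_free=eps_free, eps_pl=coef[0], eps_pl2=coef[1]
        )
    return FitResult(
        params={k: float(v) for k, v in params.items()},
        residual_norm=float(np.linalg.norm(best.fun)),
        converged=bool(best.success and not singular),
        model=model,
    )


def one_site_bound(protein_total, ligand_total, kd):
    """Closed-form [PL] of 1:1 binding (quadratic root, numerically safe branch)."""
    b = protein_total + ligand_total + kd
    disc = b * b - 4.0 * protein_total * ligand_total
    return 0.5 * (b - np.sqrt(np.maximum(disc, 0.0)))


def fit_one_site(
    exp: TitrationExperiment,
    initial_guess: float | None = None,
    include_free: bool = False,
    n_starts: int = 5,
) -> FitResult:
    """1:1 binding fit (protein monomer + ligand), closed-form bound fraction.

    The signal coefficient (and optionally a free-ligand coefficient) is
    profiled out linearly; the search runs over log10 K_D.
    """
    if len(exp.ligand_totals) < 6:
        raise ValueError("need at least 6 titration points")
    y = exp.observed
    lt = exp.ligand_totals
    pt = exp.protein_total

    def design(kd):
        pl = one_site_bound(pt, lt, kd)
        cols = [pl]
        if include_free:
            cols.append(lt - pl)
        return np.column_stack(cols)

    def residuals(logkd):
        A = design(10.0 ** logkd[0])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        return A @ coef - y

    span = np.log10(max(lt.max(), 1e-12))
    starts = [span - i for i in (0.5, 1.0, 2.0, 3.0, 4.0)][: max(1, n_starts)]
    if initial_guess is not None:
        starts.append(np.log10(initial_guess))
    best = None
    for s in starts:
        sol = least_squares(residuals, x0=np.array([s]), method="trf", xtol=1e-14)
        if best is None or sol.cost < best.cost:
            best = sol
    kd = float(10.0 ** best.x[0])
    A = design(kd)
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    params = {"kd": kd, "s_pl": float(coef[0])}
    if include_free:
        params["s_free"] = float(coef[1])
    return FitResult(
        params=params,
        residual_norm=float(np.linalg.norm(best.fun)),
        converged=bool(best.success),
    )


def average_lifetime(amplitudes, lifetimes) -> float:
    """Amplitude-weighted mean lifetime: sum(a_i tau_i) / sum(a_i)."""
    a = np.asarray(amplitudes, dtype=float)
    t = np.asarray(lifetimes, dtype=float)
    if a.shape != t.shape:
        raise ValueError("amplitudes and lifetimes must have equal length")
    if np.any(a < 0) or a.sum() <= 0:
        raise ValueError("amplitudes must be non-negative with positive sum")
    return float((a * t).sum() / a.sum())


def fret_efficiency(tau_donor: float, tau_donor_acceptor: float) -> float:
    """Energy-transfer efficiency from donor lifetimes: E = 1 - tau_DA / tau_D."""
    if tau_donor <= 0 or tau_donor_acceptor <= 0:
        raise ValueError("lifetimes must be positive")
    if tau_donor_acceptor > tau_donor:
        raise ValueError("tau_DA must not exceed tau_D")
    return 1.0 - tau_donor_acceptor / tau_donor
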