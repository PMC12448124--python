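"""Global target analysis of transient-absorption matrices.

The model is bilinear: ``dA(t, lambda) = C(theta)(t) . S(lambda)^T`` with
compartment concentrations C determined by a kinetic scheme (nonlinear
parameters theta: rates, IRF) and component spectra S conditionally linear.
Fitting uses *variable projection*: for each trial theta the spectra are
eliminated by per-wavelength linear least squares, and only theta is
iterated (trust-region reflective, rates in log10 space).

Per-compartment spectral zero-constraints ("species X does not absorb in
this wavelength range") are supported; they are the standard device for
resolving the rotational ambiguity of target models whose compartment count
equals their number of kinetic eigenmodes.

The recovered component spectra can be viewed as

* SAS - species-associated spectra of the target scheme itself,
* DAS - decay-associated spectra (equivalent parallel/eigenbasis model),
* EAS - evolution-associated spectra (equivalent unbranched sequential
  model with the same lifetimes);

all three reconstruct the identical model matrix.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping

import numpy as np
from scipy.optimize import least_squares

from .kinetics import (
    DegenerateSchemeWarning,
    KineticScheme,
    concentrations,
    observed_time_constants,
    rate_matrix,
)
from .ta import TAMatrix  # noqa: F401  (re-exported: the fit's data container)

__all__ = [
    "TAMatrix",
    "Parameter",
    "ModelSpec",
    "FitOptions",
    "FitResult",
    "project_spectra",
    "fit_global",
    "spectra_transform",
    "svd_rank",
    "model_for_preset",
]


@dataclass
class Parameter:
    """One nonlinear model parameter: initial value, free/fixed flag, bounds
    and whether it is optimized in log10 space (positivity by construction)."""

    name: str
    value: float
    vary: bool = True
    min: float = -np.inf
    max: float = np.inf
    log10: bool = False

    def __post_init__(self) -> None:
        if self.vary and not (np.isfinite(self.min) and np.isfinite(self.max)):
            raise ValueError(f"free parameter {self.name!r} needs finite bounds")
        if self.log10 and self.min <= 0:
            raise ValueError(f"log10 parameter {self.name!r} needs positive bounds")
        if not self.min <= self.value <= self.max:
            raise ValueError(
                f"parameter {self.name!r} value {self.value} outside "
                f"[{self.min}, {self.max}]"
            )


@dataclass
class ModelSpec:
    """A kinetic scheme template with named nonlinear parameters.

    ``build_scheme`` maps a full parameter mapping to a
    :class:`~photokin.kinetics.KineticScheme`; ``spectral_zero`` lists
    ``(species_label, lo_nm, hi_nm)`` ranges where that species' spectrum is
    constrained to zero.  ``offset_component`` records that the scheme
    contains a static (non-decaying) compartment.
    """

    parameters: dict[str, Parameter]
    build_scheme: Callable[[Mapping[str, float]], KineticScheme]
    spectral_zero: tuple[tuple[str, float, float], ...] = ()
    offset_component: bool = False

    def __post_init__(self) -> None:
        if not any(p.vary for p in self.parameters.values()):
            raise ValueError("model must have at least one free parameter")

    def free_names(self) -> list[str]:
        return [n for n, p in self.parameters.items() if p.vary]

    def active_mask(self, wavelengths: np.ndarray, labels: tuple[str, ...]) -> np.ndarray:
        """Boolean (n_wl, n_comp): True where a species may absorb."""
        active = np.ones((wavelengths.size, len(labels)), dtype=bool)
        for lab, lo, hi in self.spectral_zero:
            if lab in labels:
                j = labels.index(lab)
                active[(wavelengths >= lo) & (wavelengths <= hi), j] = False
        return active


@dataclass
class FitOptions:
    """Optimizer options: multi-start count and jitter, RNG seed, whether to
    exclude delays before -3 sigma of the IRF, and trust-region tolerances."""

    n_starts: int = 5
    jitter: float = 0.2
    seed: int = 0
    exclude_before_irf: bool = True
    ftol: float = 1e-10
    xtol: float = 1e-10
    max_nfev: int | None = None


@dataclass
class FitResult:
    """Outcome of a global fit.

    ``data.values == reconstruction + residual_matrix`` exactly, and ``cost``
    is the sum of squared residuals over the fitted delay range.
    """

    parameters: dict[str, float]
    stderr: dict[str, float | None]
    time_constants: np.ndarray
    compartments: tuple[str, ...]
    wavelengths: np.ndarray
    spectra: np.ndarray            # SAS, (n_wl, n_comp)
    residual_matrix: np.ndarray    # full grid, (n_wl, n_delay)
    cost: float
    converged: bool
    n_iter: int
    scheme: KineticScheme
    data: TAMatrix
    fitted_delay_mask: np.ndarray
    model: ModelSpec | None = None

    @property
    def sas(self) -> dict[str, np.ndarray]:
        return {lab: self.spectra[:, j] for j, lab in enumerate(self.compartments)}

    @property
    def reconstruction(self) -> np.ndarray:
        return self.data.values - self.residual_matrix

    def to_dict(self) -> dict:
        return {
            "parameters": {k: float(v) for k, v in self.parameters.items()},
            "stderr": {
                k: (None if v is None else float(v)) for k, v in self.stderr.items()
            },
            "time_constants_ps": [float(t) for t in self.time_constants],
            "compartments": list(self.compartments),
            "wavelengths_nm": [float(w) for w in self.wavelengths],
            "sas_mOD": {k: [float(x) for x in v] for k, v in self.sas.items()},
            "cost": float(self.cost),
            "converged": bool(self.converged),
            "n_iter": int(self.n_iter),
        }


def _masked_lstsq(C: np.ndarray, D: np.ndarray, active: np.ndarray | None):
    """Solve min ||D - C S^T|| per wavelength with optional per-wavelength
    active-column masks.  C: (n_t, n_comp); D: (n_t, n_wl);
    active: (n_wl, n_comp) or None.  Returns S (n_wl, n_comp) and the
    reconstruction (n_t, n_wl)."""
    n_t, n_comp = C.shape
    n_wl = D.shape[1]
    S = np.zeros((n_wl, n_comp))
    if active is None or bool(np.all(active)):
        coeff, *_ = np.linalg.lstsq(C, D, rcond=None)
        S = coeff.T
        return S, C @ coeff
    recon = np.zeros_like(D)
    patterns, inverse = np.unique(active, axis=0, return_inverse=True)
    for p_idx, pattern in enumerate(patterns):
        wls = np.nonzero(inverse == p_idx)[0]
        if not pattern.any():
            continue
        sub = C[:, pattern]
        coeff, *_ = np.linalg.lstsq(sub, D[:, wls], rcond=None)
        S[np.ix_(wls, np.nonzero(pattern)[0])] = coeff.T
        recon[:, wls] = sub @ coeff
    return S, recon


def project_spectra(C: np.ndarray, data: TAMatrix,
                    active: np.ndarray | None = None):
    """Conditionally linear stage of global analysis.

    Given concentrations ``C`` (one row per delay of ``data``, one column
    per transient compartment), solves ``spectra = argmin ||data - C S^T||``
    by per-wavelength linear least squares and returns ``(spectra,
    residual)`` with spectra of shape (n_wl, n_comp) and residual on the
    data layout (n_wl, n_delay).  Rank-deficient C is rejected with a
    condition-number report.
    """
    C = np.atleast_2d(np.asarray(C, dtype=float))
    if C.shape[0] != data.delays.size:
        raise ValueError(
            f"C has {C.shape[0]} rows but data has {data.delays.size} delays"
        )
    cond = np.linalg.cond(C)
    if not np.isfinite(cond) or cond > 1e10:
        raise ValueError(
            f"concentration matrix is rank deficient (condition number {cond:.3e})"
        )
    D = data.values.T
    S, recon = _masked_lstsq(C, D, active)
    return S, data.values - recon.T


def _transform(value: float, p: Parameter) -> float:
    return np.log10(value) if p.log10 else value


def _untransform(x: float, p: Parameter) -> float:
    return 10.0**x if p.log10 else x


def fit_global(data: TAMatrix, model: ModelSpec,
               init: Mapping[str, float] | None = None,
               options: FitOptions | None = None) -> FitResult:
    """Variable-projection global fit of a TA matrix to a kinetic scheme.

    ``init`` overrides the models' parameter starting values (natural
    units); all starting values must lie within bounds.  The fit is
    deterministic for fixed data, init and options (multi-start jitter is
    seeded).  On non-convergence the best point found is returned with
    ``converged=False``.
    """
    options = options or FitOptions()
    params = {n: replace(p) for n, p in model.parameters.items()}
    if init:
        for name, value in init.items():
            if name not in params:
                raise ValueError(f"unknown parameter {name!r}")
            params[name].value = float(value)
    for p in params.values():
        if not p.min <= p.value <= p.max:
            raise ValueError(
                f"initial value of {p.name!r} ({p.value}) outside bounds "
                f"[{p.min}, {p.max}]"
            )

    free = [params[n] for n in params if params[n].vary]
    x0 = np.array([_transform(p.value, p) for p in free])
    lo = np.array([_transform(p.min, p) for p in free])
    hi = np.array([_transform(p.max, p) for p in free])

    scheme0 = model.build_scheme({n: p.value for n, p in params.items()})
    labels = scheme0.transient_compartments
    if options.exclude_before_irf:
        mask = data.delays >= scheme0.irf_center - 3.0 * scheme0.irf_sigma
        if not mask.any():
            raise ValueError("all delays excluded by the IRF cut")
    else:
        mask = np.ones(data.delays.size, dtype=bool)
    t_fit = data.delays[mask]
    D_fit = data.values[:, mask].T  # (n_t, n_wl)
    active = model.active_mask(data.wavelengths, labels)

    def build(x: np.ndarray) -> KineticScheme:
        vals = {n: p.value for n, p in params.items()}
        for xi, p in zip(x, free):
            vals[p.name] = _untransform(xi, p)
        return model.build_scheme(vals)

    def residual(x: np.ndarray) -> np.ndarray:
        scheme = build(x)
        C = concentrations(scheme, t_fit).transient(scheme.ground).values.T
        _, recon = _masked_lstsq(C, D_fit, active)
        return (D_fit - recon).ravel()

    rng = np.random.default_rng(options.seed)
    starts = [x0]
    for _ in range(options.n_starts - 1):
        x = x0.copy()
        for i, p in enumerate(free):
            if p.log10:
                x[i] += rng.uniform(-options.jitter, options.jitter)
            else:
                span = hi[i] - lo[i]
                x[i] += rng.uniform(-options.jitter, options.jitter) * 0.5 * span
        starts.append(np.clip(x, lo, hi))

    best = None
    errors: list[str] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", DegenerateSchemeWarning)
        for x_start in starts:
            try:
                res = least_squares(
                    residual, x_start, bounds=(lo, hi), method="trf",
                    ftol=options.ftol, xtol=options.xtol,
                    max_nfev=options.max_nfev, x_scale="jac",
                )
            except (np.linalg.LinAlgError, ValueError) as err:  # pragma: no cover
                errors.append(str(err))
                continue
            if best is None or res.cost < best.cost:
                best = res
    if best is None:
        raise RuntimeError(f"all fit starts failed: {errors}")

    theta = {n: p.value for n, p in params.items()}
    for xi, p in zip(best.x, free):
        theta[p.name] = _untransform(xi, p)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", DegenerateSchemeWarning)
        scheme_hat = model.build_scheme(theta)
        C_fit = concentrations(scheme_hat, t_fit).transient(scheme_hat.ground).values.T
        S, _ = _masked_lstsq(C_fit, D_fit, active)
        C_full = concentrations(scheme_hat, data.delays).transient(scheme_hat.ground)
        tau = observed_time_constants(scheme_hat)

    recon_full = S @ C_full.values  # (n_wl, n_delay)
    residual_full = data.values - recon_full
    cost = float(np.sum(best.fun**2))

    # approximate standard errors from the Jacobian at the optimum
    stderr: dict[str, float | None] = {n: None for n in params}
    dof = best.fun.size - best.x.size
    if dof > 0:
        try:
            JTJ = best.jac.T @ best.jac
            cov_x = np.linalg.pinv(JTJ) * (cost / dof)
            sd_x = np.sqrt(np.clip(np.diag(cov_x), 0.0, None))
            for sd, p in zip(sd_x, free):
                stderr[p.name] = (
                    float(np.log(10.0) * theta[p.name] * sd) if p.log10 else float(sd)
                )
        except np.linalg.LinAlgError:  # pragma: no cover
            pass

    return FitResult(
        parameters=theta,
        stderr=stderr,
        time_constants=tau,
        compartments=labels,
        wavelengths=data.wavelengths,
        spectra=S,
        residual_matrix=residual_full,
        cost=cost,
        converged=bool(best.status > 0),
        n_iter=int(best.nfev),
        scheme=scheme_hat,
        data=data,
        fitted_delay_mask=mask,
        model=model,
    )


def _eig_sorted(K: np.ndarray):
    """Eigendecomposition with eigenvalues sorted ascending (fastest decay
    first); tiny deterministic perturbation if defective."""
    lam, V = np.linalg.eig(K)
    if np.linalg.cond(V) > 1e8:
        K = K * (1.0 + 1e-9 * np.arange(1, K.size + 1).reshape(K.shape))
        lam, V = np.linalg.eig(K)
    if np.max(np.abs(lam.imag)) > 1e-9 * max(np.max(np.abs(lam.real)), 1e-30):
        raise ValueError("complex kinetic eigenvalues: cannot form DAS/EAS")
    order = np.argsort(lam.real)
    return lam.real[order], V.real[:, order]


def spectra_transform(fit: FitResult, mode: str) -> tuple[list[str], np.ndarray]:
    """Recast the fitted component spectra as SAS, DAS or EAS.

    Returns ``(labels, matrix)`` with one spectrum per column.  DAS columns
    are labelled by their lifetimes; EAS columns by their sequential stage.
    All three representations reconstruct the identical model matrix.
    """
    if not fit.converged:
        raise ValueError("spectra_transform requires a converged fit")
    key = mode.upper()
    if key not in ("SAS", "DAS", "EAS"):
        raise ValueError(f"unknown mode {mode!r}; use 'SAS', 'DAS' or 'EAS'")
    if key == "SAS":
        return list(fit.compartments), fit.spectra.copy()

    scheme = fit.scheme
    all_labels = list(scheme.compartments)
    idx = [all_labels.index(lab) for lab in fit.compartments]
    K_t = rate_matrix(scheme)[np.ix_(idx, idx)]
    p0 = scheme.initial_vector()[idx]
    lam, V = _eig_sorted(K_t)
    a = np.linalg.solve(V, p0)
    W = V * a  # (n_comp, n_modes); C_target = E W^T
    das = fit.spectra @ W
    tau = np.where(np.abs(lam) > 1e-12, -1.0 / np.where(lam == 0, 1.0, lam), np.inf)
    if key == "DAS":
        labels = [
            ("tau=inf" if not np.isfinite(t) else f"tau={t:.4g} ps") for t in tau
        ]
        return labels, das

    # EAS: unbranched sequential chain 1 -> 2 -> ... with the same lifetimes
    # (fastest first), initial population in stage 1 only.
    m = lam.size
    k = -lam  # chain rates, descending
    K_chain = np.diag(-k) + np.diag(k[:-1], -1)
    lam_c, Vc = _eig_sorted(K_chain)
    e1 = np.zeros(m)
    e1[0] = np.abs(p0).sum() if np.abs(p0).sum() > 0 else 1.0
    ac = np.linalg.solve(Vc, e1)
    W_chain = Vc * ac
    # _eig_sorted orders both bases identically (eigenvalues coincide)
    eas = das @ np.linalg.inv(W_chain)
    labels = [f"EAS{j + 1}" for j in range(m)]
    return labels, eas


def svd_rank(data: TAMatrix, noise_sigma: float) -> int:
    """Number of singular values above the noise edge — a diagnostic for the
    number of spectrally distinct transient compartments.

    The threshold is the Marchenko-Pastur bulk edge for an i.i.d. Gaussian
    noise matrix, sigma*(sqrt(m)+sqrt(n)), inflated by a three-sigma
    Tracy-Widom fluctuation allowance so that pure-noise matrices almost
    never produce a false component.
    """
    if data.values.size == 0:
        raise ValueError("empty data matrix")
    m, n = data.values.shape
    s = np.linalg.svd(data.values, compute_uv=False)
    edge = np.sqrt(m) + np.sqrt(n)
    tw_scale = edge * (1.0 / np.sqrt(m) + 1.0 / np.sqrt(n)) ** (1.0 / 3.0)
    threshold = noise_sigma * np.sqrt(edge**2 + 3.0 * tw_scale)
    floor = s[0] * max(m, n) * np.finfo(float).eps
    return int(np.count_nonzero(s > max(threshold, floor)))


def model_for_preset(name: str) -> ModelSpec:
    """Fit models matching the bundled synthetic presets.

    Starting values are round plausible guesses (not the generator truth);
    rates/lifetimes are optimized in log10 space, the IRF width is bounded
    to [0.02, 0.3] ps.  The fap560 model constrains the excited-state and
    secondary-acceptor spectra to zero above 620 nm — only the
    hydrated-electron compartment absorbs in the red — which pins down the
    target model's rotational freedom, including the branching fraction phi.
    """
    from . import synthetic  # deferred: synthetic imports kinetics only

    irf = {
        "irf_center": Parameter("irf_center", 0.0, True, -0.3, 0.3),
        "irf_fwhm": Parameter("irf_fwhm", 0.12, True, 0.02, 0.3, log10=True),
    }
    if name == "fap560":
        pars = {
            "tau2": Parameter("tau2", 3.0, True, 0.3, 20.0, log10=True),
            "tau_slow": Parameter("tau_slow", 30.0, True, 5.0, 500.0, log10=True),
            "phi": Parameter("phi", 0.45, True, 0.05, 0.95),
            "rho": Parameter("rho", 0.35, True, 0.02, 0.7),
            **irf,
        }

        def build(v: Mapping[str, float]) -> KineticScheme:
            return synthetic.fap560_scheme(
                tau2=v["tau2"], tau_slow=v["tau_slow"], phi=v["phi"],
                rho=v["rho"], irf_center=v["irf_center"], irf_fwhm=v["irf_fwhm"],
            )

        return ModelSpec(
            pars, build,
            spectral_zero=(("D1star", 620.0, np.inf), ("FADox_X", 620.0, np.inf)),
        )
    if name == "fap390":
        pars = {
            "tau_cool": Parameter("tau_cool", 3.0, True, 0.3, 15.0, log10=True),
            "tau_ret": Parameter("tau_ret", 30.0, True, 5.0, 500.0, log10=True),
            **irf,
        }

        def build(v: Mapping[str, float]) -> KineticScheme:
            return synthetic.fap390_scheme(
                tau_cool=v["tau_cool"], tau_ret=v["tau_ret"],
                irf_center=v["irf_center"], irf_fwhm=v["irf_fwhm"],
            )

        return ModelSpec(pars, build, offset_component=True)
    if name == "gox520":
        pars = {
            "tau": Parameter("tau", 15.0, True, 1.0, 200.0, log10=True),
            **irf,
        }

        def build(v: Mapping[str, float]) -> KineticScheme:
            return synthetic.gox520_scheme(
                tau=v["tau"], irf_center=v["irf_center"], irf_fwhm=v["irf_fwhm"],
            )

        return ModelSpec(pars, build)
    raise ValueError(f"unknown preset {name!r}; valid presets: fap560, fap390, gox520")
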