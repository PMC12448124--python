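"""First-order compartmental kinetics convolved with a Gaussian instrument response.

A photocycle is modelled as a closed network of compartments (species) with
first-order transfer rates, one of which is a designated ground/terminal
compartment.  Excitation deposits population according to
``initial_populations`` (fractions at t = 0+, i.e. after any sub-IRF
branching), smeared in time by a Gaussian instrument response function (IRF).

The population of every compartment is obtained in closed form from the
eigendecomposition of the rate matrix: each eigenmode decays exponentially,
and an exponential convolved with a normalized Gaussian has the analytic
exp*erfc form implemented in :func:`expgauss`.

Units: time in ps, rates in ps^-1.  Reported time constants are tau = 1/k.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import erfc, erfcx

__all__ = [
    "KineticScheme",
    "ConcentrationMatrix",
    "DegenerateSchemeWarning",
    "rate_matrix",
    "expgauss",
    "concentrations",
    "observed_time_constants",
]

# fwhm = 2*sqrt(2 ln 2) * sigma
_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


class DegenerateSchemeWarning(UserWarning):
    """Raised when a scheme's rate matrix is (near-)defective and rates are
    perturbed to restore diagonalizability."""


@dataclass(frozen=True)
class KineticScheme:
    """A closed first-order compartmental scheme with a Gaussian IRF.

    Parameters
    ----------
    compartments:
        Ordered species labels, including the ground/terminal label.
    rates:
        Mapping ``(from_label, to_label) -> rate constant`` in ps^-1.
        Every loss from one compartment is a gain to another (the scheme is
        closed by construction); rates must be non-negative.
    initial_populations:
        Per-compartment population fractions at t = 0+ (post-branching).
        Must be non-negative and sum to <= 1; the remainder starts in the
        ground compartment.
    ground:
        Label of the ground compartment (no spectrum, receives recovery).
    irf_center, irf_fwhm:
        Gaussian IRF position and full width at half maximum, in ps.
    """

    compartments: tuple[str, ...]
    rates: dict[tuple[str, str], float]
    initial_populations: dict[str, float]
    ground: str = "ground"
    irf_center: float = 0.0
    irf_fwhm: float = 0.1

    def __post_init__(self) -> None:
        if len(set(self.compartments)) != len(self.compartments):
            raise ValueError("compartment labels must be unique")
        if self.ground not in self.compartments:
            raise ValueError(f"ground label {self.ground!r} not in compartments")
        for (a, b), k in self.rates.items():
            if a not in self.compartments or b not in self.compartments:
                raise ValueError(
                    f"rate ({a!r} -> {b!r}) references unknown compartment; "
                    "scheme must be closed"
                )
            if a == b:
                raise ValueError(f"self-rate on {a!r} is not allowed")
            if not np.isfinite(k) or k < 0:
                raise ValueError(f"rate ({a!r} -> {b!r}) = {k} must be finite and >= 0")
        total = 0.0
        for lab, p in self.initial_populations.items():
            if lab not in self.compartments:
                raise ValueError(f"initial population for unknown compartment {lab!r}")
            if not np.isfinite(p) or p < 0:
                raise ValueError(f"initial population of {lab!r} must be >= 0")
            total += p
        if total > 1.0 + 1e-9:
            raise ValueError(f"initial populations sum to {total} > 1")
        if not self.irf_fwhm > 0:
            raise ValueError("irf_fwhm must be > 0")

    @property
    def irf_sigma(self) -> float:
        """Gaussian IRF standard deviation (ps)."""
        return self.irf_fwhm * _FWHM_TO_SIGMA

    @property
    def transient_compartments(self) -> tuple[str, ...]:
        """All compartments except the ground one, in scheme order."""
        return tuple(c for c in self.compartments if c != self.ground)

    def initial_vector(self) -> np.ndarray:
        """Initial populations as a vector in compartment order; the ground
        compartment absorbs the remainder to 1."""
        p0 = np.array(
            [self.initial_populations.get(c, 0.0) for c in self.compartments]
        )
        i_g = self.compartments.index(self.ground)
        p0[i_g] += 1.0 - p0.sum()
        return p0

    def with_irf(self, center: float | None = None, fwhm: float | None = None) -> "KineticScheme":
        return replace(
            self,
            irf_center=self.irf_center if center is None else center,
            irf_fwhm=self.irf_fwhm if fwhm is None else fwhm,
        )


@dataclass
class ConcentrationMatrix:
    """Per-compartment populations on a delay grid.

    ``values[i, j]`` is the population of ``labels[i]`` at ``delays[j]``.
    The sum over all compartments (ground included) at each delay equals the
    cumulative IRF at that delay.
    """

    labels: tuple[str, ...]
    delays: np.ndarray
    values: np.ndarray

    def __getitem__(self, label: str) -> np.ndarray:
        return self.values[self.labels.index(label)]

    def transient(self, ground: str = "ground") -> "ConcentrationMatrix":
        keep = [i for i, lab in enumerate(self.labels) if lab != ground]
        return ConcentrationMatrix(
            tuple(self.labels[i] for i in keep), self.delays, self.values[keep]
        )

    def to_csv(self, path) -> None:
        """Write in the delimited TA dialect (compartments as rows)."""
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("compartment," + ",".join(f"{t:.10g}" for t in self.delays) + "\n")
            for lab, row in zip(self.labels, self.values):
                fh.write(lab + "," + ",".join(f"{v:.10g}" for v in row) + "\n")


def rate_matrix(scheme: KineticScheme) -> np.ndarray:
    """Build the square rate matrix K (ps^-1) of a closed scheme.

    ``K[i, j]`` is the rate j -> i for i != j and ``K[j, j]`` is minus the sum
    of all losses from j, so columns sum to zero.
    """
    n = len(scheme.compartments)
    idx = {lab: i for i, lab in enumerate(scheme.compartments)}
    K = np.zeros((n, n))
    for (a, b), k in scheme.rates.items():
        ia, ib = idx[a], idx[b]
        K[ib, ia] += k
        K[ia, ia] -= k
    return K


def expgauss(k, t, mu: float, sigma: float):
    """Exponential decay exp(-k t) convolved with a normalized Gaussian IRF.

    Evaluates ``0.5 * exp(k*(mu + k*sigma^2/2 - t)) * erfc((mu + k*sigma^2 - t)
    / (sqrt(2)*sigma))`` — the analytic convolution of a unit-amplitude,
    k-rate exponential (switched on at the IRF) with a Gaussian of mean ``mu``
    and width ``sigma``.  For ``k = 0`` this reduces to the cumulative
    Gaussian step.

    The naive formula overflows for large ``k*sigma``; wherever the erfc
    argument is positive the scaled complement ``erfcx`` is used instead,
    keeping the evaluation stable for k*sigma up to ~1e3.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    k = np.asarray(k, dtype=float)
    if np.any(k < 0):
        raise ValueError("k must be >= 0")
    t = np.asarray(t, dtype=float)
    z = (mu + k * sigma**2 - t) / (np.sqrt(2.0) * sigma)
    with np.errstate(over="ignore", invalid="ignore"):
        # z <= 0: direct evaluation is safe (the exponent is bounded there;
        # the overflow in the discarded z > 0 lanes is masked out below)
        direct = 0.5 * np.exp(k * (mu + 0.5 * k * sigma**2 - t)) * erfc(z)
        # z > 0: exp(a)*erfc(z) = exp(a - z^2)*erfcx(z) with a - z^2 =
        # -(t-mu)^2/(2 sigma^2), always <= 0.
        safe = 0.5 * np.exp(-((t - mu) ** 2) / (2.0 * sigma**2)) * erfcx(z)
        out = np.where(z > 0, safe, direct)
    return out if out.shape else float(out)


def _eigen_system(scheme: KineticScheme):
    """Eigendecomposition of the rate matrix; perturbs rates if defective.

    Near-degenerate *defective* matrices (Jordan blocks) cannot be expanded in
    pure exponentials; following standard global-analysis practice the rates
    are then perturbed by a relative 1e-9 (deterministically, per rate index)
    and a :class:`DegenerateSchemeWarning` is emitted.  Degenerate but
    diagonalizable cases (e.g. two non-decaying compartments) pass through
    untouched.
    """
    K = rate_matrix(scheme)
    lam, V = np.linalg.eig(K)
    if np.linalg.cond(V) > 1e8:
        warnings.warn(
            "rate matrix is (near-)defective; perturbing rates by 1e-9 "
            "relative to restore diagonalizability",
            DegenerateSchemeWarning,
            stacklevel=3,
        )
        pert = {
            pair: k * (1.0 + 1e-9 * (i + 1))
            for i, (pair, k) in enumerate(sorted(scheme.rates.items()))
        }
        K = rate_matrix(replace(scheme, rates=pert))
        lam, V = np.linalg.eig(K)
    if np.max(np.abs(lam.imag)) > 1e-9 * max(np.max(np.abs(lam.real)), 1e-30):
        raise ValueError(
            "rate matrix has complex eigenvalues (cyclic scheme); "
            "only real-mode schemes are supported"
        )
    return lam.real, V.real


def concentrations(scheme: KineticScheme, delays) -> ConcentrationMatrix:
    """Closed-form compartment populations at the given delays.

    c(t) = sum_m v_m a_m expgauss(-lambda_m, t, mu, sigma) where (lambda_m,
    v_m) are eigenpairs of the rate matrix and a = V^-1 c0.  Satisfies
    population conservation: the per-delay sum over all compartments equals
    the cumulative IRF.
    """
    delays = np.asarray(delays, dtype=float)
    lam, V = _eigen_system(scheme)
    a = np.linalg.solve(V, scheme.initial_vector())
    mu, sigma = scheme.irf_center, scheme.irf_sigma
    # eigenvalues of a closed scheme are <= 0; clip tiny positive noise
    kdec = np.clip(-lam, 0.0, None)
    E = np.stack([expgauss(k, delays, mu, sigma) for k in kdec])  # (m, t)
    values = (V * a) @ E  # (n_comp, t)
    return ConcentrationMatrix(tuple(scheme.compartments), delays, values)


def observed_time_constants(scheme: KineticScheme) -> np.ndarray:
    """Lifetimes -1/Re(lambda) of the nonzero rate-matrix eigenvalues,
    ascending — the time constants an observer extracts from a global fit."""
    K = rate_matrix(scheme)
    lam = np.linalg.eigvals(K).real
    scale = max(np.max(np.abs(lam)), 1e-30)
    nonzero = lam[np.abs(lam) > 1e-12 * scale]
    return np.sort(-1.0 / nonzero)
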