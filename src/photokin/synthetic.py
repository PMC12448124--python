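"""Synthetic transient-absorption datasets and toy active-site trajectories.

The generator encodes, as bundled presets, three flavin-radical photocycles
observed by pump-probe spectroscopy:

``fap560``
    Excitation of the anionic flavin radical (FAD.-) D1 state in a fatty
    acid photodecarboxylase.  Within the instrument response, ~50% of the
    excited enzymes form oxidized flavin paired with a hydrated electron
    ([FADox e-H]); the rest remain in the excited radical state (D1*) and
    convert with a ~2.5-ps delay.  The hydrated-electron state equilibrates
    (net 2.5 ps) with a lower-lying acceptor state [FADox X-], and the
    whole ensemble recombines to the radical ground state in 37 ps.
``fap390``
    D2 excitation: quasi-immediate formation of a vibrationally hot FADox
    state that cools (band narrowing) in ~2.2 ps, returns in 37 ps, plus a
    static long-lived component from a two-electron-reduced fraction
    outside the photocycle.
``gox520``
    Glucose oxidase control: a single transient compartment
    ([FADox acceptor-]) decaying in ~20 ps.

All transient compartments carry *difference* spectra: the ground-state
(FAD.-) absorption is folded in as negative Gaussian bands (bleach), and the
ground compartment has an identically zero spectrum — that is what a
pump-probe experiment measures.  The forward model is
``dA = S(wavelengths) @ C(scheme, delays)`` plus seeded Gaussian noise.

The toy trajectories emulate the MD observations the hydration analytics
are aimed at: a probe group (an arginine guanidinium stand-in) whose
distance to a flavin-ring stand-in follows a configurable schedule between
~4.2 and ~6.5 A, and a pocket whose water occupancy is Poisson with a
configurable mean (optionally coupled to the probe distance).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .hydration import Frame, Trajectory
from .kinetics import KineticScheme, concentrations
from .ta import TAMatrix

__all__ = [
    "BandSpec",
    "ComponentSpectrum",
    "SyntheticSpec",
    "ToyTrajectoryConfig",
    "PRESETS",
    "build_preset",
    "simulate_ta",
    "make_toy_trajectory",
    "default_wavelengths",
    "default_delays",
    "fap560_scheme",
    "fap390_scheme",
    "gox520_scheme",
    "save_preset",
    "load_preset",
]

PRESETS = ("fap560", "fap390", "gox520")

_FOUR_LN2 = 4.0 * np.log(2.0)


@dataclass(frozen=True)
class BandSpec:
    """One Gaussian band: center (nm), FWHM (nm) and signed peak height
    (mOD); positive = induced absorption, negative = bleach / stimulated
    emission.  Bands are Gaussian in wavelength space."""

    center: float
    fwhm: float
    amplitude: float

    def __post_init__(self) -> None:
        if not self.fwhm > 0:
            raise ValueError("band fwhm must be > 0")
        if not 300.0 <= self.center <= 900.0:
            raise ValueError("band center must lie within 300-900 nm")

    def evaluate(self, wavelengths: np.ndarray) -> np.ndarray:
        wl = np.asarray(wavelengths, dtype=float)
        return self.amplitude * np.exp(
            -_FOUR_LN2 * (wl - self.center) ** 2 / self.fwhm**2
        )


@dataclass(frozen=True)
class ComponentSpectrum:
    """Difference spectrum of one species as a sum of Gaussian bands."""

    species_label: str
    bands: tuple[BandSpec, ...]

    def evaluate(self, wavelengths: np.ndarray) -> np.ndarray:
        wl = np.asarray(wavelengths, dtype=float)
        out = np.zeros_like(wl)
        for band in self.bands:
            out += band.evaluate(wl)
        return out


@dataclass
class SyntheticSpec:
    """Complete recipe for one synthetic TA dataset."""

    scheme: KineticScheme
    spectra: tuple[ComponentSpectrum, ...]
    wavelength_grid: np.ndarray
    delay_grid: np.ndarray
    noise_sigma: float = 0.1
    seed: int = 1
    excitation_nm: float | None = None

    def __post_init__(self) -> None:
        self.wavelength_grid = np.asarray(self.wavelength_grid, dtype=float)
        self.delay_grid = np.asarray(self.delay_grid, dtype=float)
        labels = tuple(s.species_label for s in self.spectra)
        if labels != self.scheme.transient_compartments:
            raise ValueError(
                f"spectra labels {labels} must match the scheme's transient "
                f"compartments {self.scheme.transient_compartments} exactly"
            )
        if np.any(np.diff(self.delay_grid) <= 0):
            raise ValueError("delay_grid must be strictly increasing")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


def default_wavelengths() -> np.ndarray:
    """360-780 nm in 2-nm steps (211 points)."""
    return np.arange(360.0, 781.0, 2.0)


def default_delays() -> np.ndarray:
    """-1 to 200 ps: linear in 0.1-ps steps up to 2 ps, then log-spaced to
    200 ps; 60 points total."""
    return np.concatenate(
        [np.arange(-1.0, 2.0 + 1e-9, 0.1), np.geomspace(2.3, 200.0, 29)]
    )


# ---------------------------------------------------------------------------
# Component bands.
#
# The oxidized-flavin band parameters are calibrated so that the *composite*
# difference spectrum (positive FADox band plus the FAD.- bleach bands below)
# exhibits the experimentally observed induced-absorption band: centered at
# 460 nm with a 70-nm FWHM.  Solving that 2x2 problem on a 0.01-nm grid gives
# a component Gaussian at 468.3 nm with 86.0-nm FWHM.
# ---------------------------------------------------------------------------

#: oxidized-flavin induced absorption (composite peaks at 460 nm / 70 nm FWHM)
FADOX_BAND = BandSpec(center=468.3, fwhm=86.0, amplitude=6.0)
#: hydrated-electron band: broad, maximum near 730 nm
EH_BAND = BandSpec(center=730.0, fwhm=160.0, amplitude=3.0)
#: ground-state (FAD.-) bleach folded into every photocycle compartment
BLEACH_BANDS = (
    BandSpec(center=520.0, fwhm=110.0, amplitude=-3.0),
    BandSpec(center=368.0, fwhm=60.0, amplitude=-1.5),
)
#: vibrationally hot FADox: broader band, roughly area-conserving amplitude
HOT_FADOX_BAND = BandSpec(center=468.3, fwhm=120.0, amplitude=4.3)
#: long-lived two-electron-reduced fraction (absorbs below ~550 nm)
OFFSET_BAND = BandSpec(center=480.0, fwhm=90.0, amplitude=0.8)


def fap560_scheme(tau2: float = 2.5, tau_slow: float = 37.0, phi: float = 0.5,
                  rho: float = 0.3, irf_center: float = 0.0,
                  irf_fwhm: float = 0.1) -> KineticScheme:
    """Four-compartment target scheme for D1 excitation of FAD.-.

    Compartments: D1star (excited radical), FADox_eH ([FADox e-H]),
    FADox_X ([FADox X-]), ground.

    Parameterization (observables -> microscopic rates):

    * phi     - sub-IRF branching: initial populations (1-phi, phi, 0)
    * tau2    - the ~2.5-ps phase; sets both the delayed-formation rate
                k_d = 1/tau2 (D1star -> FADox_eH) and the relaxation rate
                of the reversible exchange, k_f + k_b = 1/tau2
    * rho     - equilibrium fraction remaining in FADox_eH:
                k_b = rho/tau2, k_f = (1-rho)/tau2
    * tau_slow- slowest observed lifetime; the ground-state recovery rate
                k_g (FADox_X -> ground) is solved from the characteristic
                quadratic of the exchange block so that its slow eigenvalue
                is exactly -1/tau_slow:
                k_g = lam_s (s - lam_s) / (k_f - lam_s),  lam_s = 1/tau_slow
    """
    if not 0.0 <= phi <= 1.0:
        raise ValueError("phi must lie in [0, 1]")
    if not 0.0 < rho < 1.0:
        raise ValueError("rho must lie in (0, 1)")
    s = 1.0 / tau2
    k_d = 1.0 / tau2
    k_b = rho * s
    k_f = (1.0 - rho) * s
    lam_s = 1.0 / tau_slow
    # guard: outside the physical branch (tau_slow ~ tau2) clamp smoothly so
    # a fit stepping there sees a finite, poor model rather than an exception
    k_g = lam_s * max(s - lam_s, 1e-6) / max(k_f - lam_s, 1e-6)
    k_g = float(np.clip(k_g, 1e-6, 1e3))
    return KineticScheme(
        compartments=("D1star", "FADox_eH", "FADox_X", "ground"),
        rates={
            ("D1star", "FADox_eH"): k_d,
            ("FADox_eH", "FADox_X"): k_f,
            ("FADox_X", "FADox_eH"): k_b,
            ("FADox_X", "ground"): k_g,
        },
        initial_populations={"D1star": 1.0 - phi, "FADox_eH": phi},
        irf_center=irf_center,
        irf_fwhm=irf_fwhm,
    )


def fap390_scheme(tau_cool: float = 2.2, tau_ret: float = 37.0,
                  offset_fraction: float = 0.1, irf_center: float = 0.0,
                  irf_fwhm: float = 0.1) -> KineticScheme:
    """D2-excitation scheme: hot FADox cools (band narrowing) in tau_cool,
    returns to ground in tau_ret; a static offset compartment holds the
    long-lived (>> 200 ps) fraction outside the photocycle."""
    if not 0.0 <= offset_fraction < 1.0:
        raise ValueError("offset_fraction must lie in [0, 1)")
    return KineticScheme(
        compartments=("hot_FADox", "FADox", "offset", "ground"),
        rates={
            ("hot_FADox", "FADox"): 1.0 / tau_cool,
            ("FADox", "ground"): 1.0 / tau_ret,
        },
        initial_populations={
            "hot_FADox": 1.0 - offset_fraction,
            "offset": offset_fraction,
        },
        irf_center=irf_center,
        irf_fwhm=irf_fwhm,
    )


def gox520_scheme(tau: float = 20.0, irf_center: float = 0.0,
                  irf_fwhm: float = 0.1) -> KineticScheme:
    """Glucose oxidase control: one transient compartment
    ([FADox acceptor-]) formed within the IRF and decaying in tau."""
    return KineticScheme(
        compartments=("FADox_acc", "ground"),
        rates={("FADox_acc", "ground"): 1.0 / tau},
        initial_populations={"FADox_acc": 1.0},
        irf_center=irf_center,
        irf_fwhm=irf_fwhm,
    )


def build_preset(name: str) -> SyntheticSpec:
    """Bundled presets with documented ground-truth parameters.

    ``fap560``: branching phi = 0.5, net 2.5-ps equilibration (rho = 0.3),
    37-ps recovery; FADox band in both product compartments, the
    hydrated-electron band (730 nm) only in [FADox e-H]; the excited-state
    compartment carries only the bleach (its induced absorption is unknown
    and deliberately left out).
    ``fap390``: 2.2-ps cooling, 37-ps return, 10% static offset.
    ``gox520``: single transient compartment, 20-ps recovery.
    """
    if name == "fap560":
        scheme = fap560_scheme()
        spectra = (
            ComponentSpectrum("D1star", BLEACH_BANDS),
            ComponentSpectrum("FADox_eH", (FADOX_BAND, EH_BAND) + BLEACH_BANDS),
            ComponentSpectrum("FADox_X", (FADOX_BAND,) + BLEACH_BANDS),
        )
        excitation = 560.0
    elif name == "fap390":
        scheme = fap390_scheme()
        spectra = (
            ComponentSpectrum("hot_FADox", (HOT_FADOX_BAND,) + BLEACH_BANDS),
            ComponentSpectrum("FADox", (FADOX_BAND,) + BLEACH_BANDS),
            ComponentSpectrum("offset", (OFFSET_BAND,)),
        )
        excitation = 390.0
    elif name == "gox520":
        scheme = gox520_scheme()
        band = BandSpec(center=458.3, fwhm=86.0, amplitude=6.0)
        spectra = (ComponentSpectrum("FADox_acc", (band,) + BLEACH_BANDS),)
        excitation = 520.0
    else:
        raise ValueError(f"unknown preset {name!r}; valid presets: {', '.join(PRESETS)}")
    return SyntheticSpec(
        scheme=scheme,
        spectra=spectra,
        wavelength_grid=default_wavelengths(),
        delay_grid=default_delays(),
        noise_sigma=0.1,
        seed=1,
        excitation_nm=excitation,
    )


def simulate_ta(spec: SyntheticSpec) -> TAMatrix:
    """Forward-model a TA matrix: dA = S @ C + Gaussian noise (seeded).

    With ``noise_sigma = 0`` the output equals the noiseless model to full
    floating precision, and its rank equals the number of spectrally
    distinct transient compartments.
    """
    conc = concentrations(spec.scheme, spec.delay_grid).transient(spec.scheme.ground)
    if conc.labels != tuple(s.species_label for s in spec.spectra):
        raise ValueError("spectra labels do not match scheme compartments")
    S = np.column_stack([s.evaluate(spec.wavelength_grid) for s in spec.spectra])
    values = S @ conc.values
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        values = values + rng.normal(0.0, spec.noise_sigma, size=values.shape)
    return TAMatrix(
        spec.wavelength_grid.copy(),
        spec.delay_grid.copy(),
        values,
        excitation_nm=spec.excitation_nm,
    )


# ---------------------------------------------------------------------------
# Preset serialization (round-trippable YAML)
# ---------------------------------------------------------------------------

def spec_to_dict(spec: SyntheticSpec) -> dict:
    sch = spec.scheme
    return {
        "scheme": {
            "compartments": list(sch.compartments),
            "ground": sch.ground,
            "rates": {f"{a}->{b}": float(k) for (a, b), k in sch.rates.items()},
            "initial_populations": {
                k: float(v) for k, v in sch.initial_populations.items()
            },
            "irf_center": float(sch.irf_center),
            "irf_fwhm": float(sch.irf_fwhm),
        },
        "spectra": [
            {
                "species_label": s.species_label,
                "bands": [[b.center, b.fwhm, b.amplitude] for b in s.bands],
            }
            for s in spec.spectra
        ],
        "wavelength_grid": [float(x) for x in spec.wavelength_grid],
        "delay_grid": [float(x) for x in spec.delay_grid],
        "noise_sigma": float(spec.noise_sigma),
        "seed": int(spec.seed),
        "excitation_nm": spec.excitation_nm,
    }


def spec_from_dict(d: dict) -> SyntheticSpec:
    sch = d["scheme"]
    rates = {}
    for key, k in sch["rates"].items():
        a, b = key.split("->")
        rates[(a, b)] = float(k)
    scheme = KineticScheme(
        compartments=tuple(sch["compartments"]),
        rates=rates,
        initial_populations=dict(sch["initial_populations"]),
        ground=sch["ground"],
        irf_center=float(sch["irf_center"]),
        irf_fwhm=float(sch["irf_fwhm"]),
    )
    spectra = tuple(
        ComponentSpectrum(
            s["species_label"], tuple(BandSpec(*map(float, b)) for b in s["bands"])
        )
        for s in d["spectra"]
    )
    return SyntheticSpec(
        scheme=scheme,
        spectra=spectra,
        wavelength_grid=np.array(d["wavelength_grid"]),
        delay_grid=np.array(d["delay_grid"]),
        noise_sigma=float(d["noise_sigma"]),
        seed=int(d["seed"]),
        excitation_nm=d.get("excitation_nm"),
    )


def save_preset(spec: SyntheticSpec, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(spec_to_dict(spec), fh, sort_keys=True)


def load_preset(path) -> SyntheticSpec:
    with open(path, encoding="utf-8") as fh:
        return spec_from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# Toy active-site trajectories
# ---------------------------------------------------------------------------

#: planar 4-atom reference group (C4, N5, N10, C9 stand-ins); the dihedral
#: over ids 0-1-2-3 of an unperturbed frame is exactly 0 deg (coplanar cis)
REF_ELEMENTS = ("C", "N", "N", "C")
REF_COORDS = np.array(
    [[-2.1, 0.7, 0.0], [-0.7, 0.0, 0.0], [0.7, 0.0, 0.0], [2.1, 0.7, 0.0]]
)
#: 3-atom probe group (guanidinium stand-in), centered on its centroid
PRB_ELEMENTS = ("N", "N", "C")
_PRB_OFFSETS = np.array([[-0.6, 0.0, 0.0], [0.6, 0.0, 0.0], [0.0, 0.8, 0.0]])
PRB_OFFSETS = _PRB_OFFSETS - _PRB_OFFSETS.mean(axis=0)

#: default seed point for pocket analysis of toy trajectories (A)
TOY_SEED_POINT = np.array([0.0, -3.5, 0.0])
#: clearance kept between placed waters and occluding atoms / the cage (A);
#: exceeds vdW + probe (3.1 A) plus half a 0.4-A cell diagonal, so placed
#: waters always land in solvent-accessible cells
_WATER_CLEARANCE = 3.6


@dataclass
class ToyTrajectoryConfig:
    """Recipe for a toy active-site trajectory.

    The occluding cage is a sphere of OCC atoms of radius ``shell_radius``
    centered on the origin; the pocket is its interior.  Per frame, the
    probe-group centroid sits at the scheduled distance from the reference
    centroid (along +x) plus isotropic Gaussian jitter, and the number of
    in-pocket waters is Poisson with mean ``mean_occupancy`` (kept constant
    over the fixed water roster by parking unused waters in a bulk shell
    outside the cage).

    ``occupancy_coupling`` couples occupancy to the probe distance: the
    per-frame Poisson mean is ``mean_occupancy * (1 + coupling * (d_t -
    <d>)/<d>)``, emulating a pocket that hydrates as the probe retreats.
    """

    n_frames: int
    probe_distance_schedule: np.ndarray
    shell_radius: float = 8.0
    mean_occupancy: float = 4.0
    jitter_sigma: float = 0.15
    seed: int = 0
    n_bulk_waters: int = 25
    occupancy_coupling: float = 0.0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        self.probe_distance_schedule = np.asarray(
            self.probe_distance_schedule, dtype=float
        )
        if self.probe_distance_schedule.shape != (self.n_frames,):
            raise ValueError(
                f"probe_distance_schedule length {self.probe_distance_schedule.size}"
                f" != n_frames {self.n_frames}"
            )
        if np.any(self.probe_distance_schedule <= 0):
            raise ValueError("all scheduled distances must be > 0")
        if self.mean_occupancy < 0:
            raise ValueError("mean_occupancy must be >= 0")
        if self.jitter_sigma < 0:
            raise ValueError("jitter_sigma must be >= 0")
        if self.shell_radius <= _WATER_CLEARANCE + 1.0:
            raise ValueError(
                f"shell_radius must exceed {_WATER_CLEARANCE + 1.0} A to leave room "
                "for pocket waters"
            )


def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def make_toy_trajectory(cfg: ToyTrajectoryConfig) -> Trajectory:
    """Generate a toy trajectory; bit-identical for a fixed seed.

    Randomness is drawn from one independent child stream per frame index
    (spawned from ``cfg.seed``), so frame i's draws do not depend on the
    schedule values of other frames.
    """
    R = cfg.shell_radius
    # cage dense enough that no probe-sized corridor crosses it
    n_shell = max(32, int(np.ceil(4.0 * np.pi * R**2 / 7.0)))
    shell = _fibonacci_sphere(n_shell) * R
    ref_centroid = REF_COORDS.mean(axis=0)
    r_water = R - _WATER_CLEARANCE

    n_pocket_slots = int(np.ceil(cfg.mean_occupancy + 6.0 * np.sqrt(cfg.mean_occupancy + 1.0) + 8.0))
    n_waters = n_pocket_slots + cfg.n_bulk_waters

    roles = np.array(
        ["REF"] * 4 + ["PRB"] * 3 + ["OCC"] * n_shell + ["HOH"] * n_waters
    )
    elements = np.array(
        list(REF_ELEMENTS) + list(PRB_ELEMENTS) + ["C"] * n_shell + ["O"] * n_waters
    )
    ids = np.arange(roles.size)

    dbar = float(cfg.probe_distance_schedule.mean())
    children = np.random.SeedSequence(cfg.seed).spawn(cfg.n_frames)
    frames = []
    for t in range(cfg.n_frames):
        rng = np.random.default_rng(children[t])
        d_t = cfg.probe_distance_schedule[t]
        centroid = ref_centroid + np.array([d_t, 0.0, 0.0])
        if cfg.jitter_sigma > 0:
            centroid = centroid + rng.normal(0.0, cfg.jitter_sigma, size=3)
        prb = centroid + PRB_OFFSETS
        occluders = np.vstack([REF_COORDS, prb])

        mean_t = cfg.mean_occupancy
        if cfg.occupancy_coupling != 0.0:
            mean_t *= max(0.0, 1.0 + cfg.occupancy_coupling * (d_t - dbar) / dbar)
        k = min(int(rng.poisson(mean_t)), n_pocket_slots) if mean_t > 0 else 0

        pocket = np.empty((k, 3))
        placed = 0
        attempts = 0
        while placed < k:
            attempts += 1
            if attempts > 2000 * max(k, 1):
                raise RuntimeError("pocket too crowded: cannot place waters")
            p = rng.uniform(-r_water, r_water, size=3)
            if np.dot(p, p) > r_water**2:
                continue
            if np.min(np.linalg.norm(occluders - p, axis=1)) <= _WATER_CLEARANCE:
                continue
            pocket[placed] = p
            placed += 1

        n_out = n_waters - k
        u = rng.random(n_out)
        rad = ((R + 6.0) ** 3 * u + (R + 3.0) ** 3 * (1.0 - u)) ** (1.0 / 3.0)
        direction = rng.normal(size=(n_out, 3))
        direction /= np.linalg.norm(direction, axis=1, keepdims=True)
        bulk = direction * rad[:, None]

        coords = np.vstack([REF_COORDS, prb, shell, pocket, bulk])
        frames.append(Frame(ids, roles, elements, coords))

    meta = {
        "seed_point": TOY_SEED_POINT.tolist(),
        "suggested_search_radius": R + 1.0,
        "pocket_water_radius": r_water,
        "n_pocket_slots": n_pocket_slots,
        "config_seed": cfg.seed,
    }
    return Trajectory(frames, box=None, meta=meta)
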