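"""Synthetic single-molecule data generators.

Every downstream stage of the package (trace screening, change-point step
counting, FRET distance histograms, two-colour colocalization, lifetime
fitting) can be exercised on data produced here.  The generators encode the
statistical structure the analysis assumes:

* per-molecule inter-dye distances drawn from a Gaussian state distribution,
  converted to FRET efficiency through ``E = 1 / (1 + (r/R0)^6)``;
* irreversible single-exponential photobleaching of each fluorophore;
* two-channel spot images rendered as Gaussian PSFs with Poisson shot noise;
* TCSPC photon delays as a window-truncated exponential.

Condition presets bundle the measured parameters of the cryptochrome system
this package was built around: a compact dark-state conformer (50 +/- 13 A
between the PHR-domain and CTE-tail dye sites), an extended lit-state
conformer (65 +/- 12 A), a compact dimer conformer (48 +/- 12 A), dark/lit
two-step bleaching fractions of 7.5% / 25.1%, and a light-dependent
bait-prey joint occupancy whose overall colocalization is ~23%.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "TraceConfig",
    "ConditionPreset",
    "Trace",
    "SpotField",
    "TcspcHistogram",
    "ConditionDataset",
    "PRESETS",
    "DEFAULT_FRET_CONFIG",
    "DEFAULT_BLEACH_CONFIG",
    "get_preset",
    "generate_fret_trace",
    "generate_bleach_trace",
    "generate_condition_dataset",
    "generate_spot_field",
    "render_spot_fields",
    "generate_tcspc",
    "sphere_points",
    "two_state_calpha_fixture",
]


# --------------------------------------------------------------------------
# configuration types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TraceConfig:
    """Parameters of a simulated intensity time trace.

    ``donor_brightness`` is the total photon budget per frame of one
    fluorophore (for FRET traces it is split between donor and acceptor
    channels according to the transfer efficiency).  Rates are per second;
    distances in Angstrom; the 0.1 s default frame interval matches the
    practical EMCCD time bin of the experiments emulated here.
    """

    frame_interval: float = 0.1        # s
    n_frames: int = 400
    donor_brightness: float = 3000.0   # counts / frame
    background_mean: float = 0.0       # counts / frame
    noise_sd: float = 150.0            # counts / frame, additive Gaussian
    gamma: float = 1.0                 # detection-correction factor
    donor_bleach_rate: float = 0.03    # 1/s
    acceptor_bleach_rate: float = 0.03  # 1/s
    r0: float = 63.0                   # Forster radius, Angstrom
    state_mean: float = 50.0           # Angstrom
    state_sd: float = 13.0             # Angstrom
    distance_jitter_mode: str = "static-per-molecule"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.r0 <= 0:
            raise ValueError("r0 must be > 0")
        if self.state_sd < 0:
            raise ValueError("state_sd must be >= 0")
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")
        if self.distance_jitter_mode not in ("static-per-molecule", "per-frame"):
            raise ValueError(
                "distance_jitter_mode must be 'static-per-molecule' or 'per-frame'"
            )

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha1(payload.encode()).hexdigest()[:12]


#: Trace parameters for two-colour FRET molecules.  The photon budget is set
#: high enough that per-frame intensity noise adds only ~2 A of distance
#: broadening, so the width of a measured histogram is dominated by the
#: conformational state SD the preset encodes (which is how the measured
#: widths are interpreted here).
DEFAULT_FRET_CONFIG = TraceConfig()

#: Trace parameters for single-colour photobleaching (stoichiometry) movies.
#: Per-frame SNR of 3.0 -- the top of the screening band used to admit
#: molecules -- and a bleach rate slow enough that two bleach events rarely
#: fall inside the same minimum detectable segment.
DEFAULT_BLEACH_CONFIG = TraceConfig(
    n_frames=3000,
    donor_brightness=300.0,
    background_mean=0.0,
    noise_sd=100.0,
    donor_bleach_rate=0.02,
    acceptor_bleach_rate=0.0,
)


def _validate_joint(cells: tuple[float, float, float, float]) -> None:
    arr = np.asarray(cells, dtype=float)
    if arr.shape != (4,):
        raise ValueError("joint_cells must have 4 entries")
    if np.any(arr < 0) or np.any(arr > 1):
        raise ValueError("joint_cells probabilities must lie in [0, 1]")
    if abs(arr.sum() - 1.0) > 1e-12:
        raise ValueError("joint_cells must sum to 1")


@dataclass(frozen=True)
class ConditionPreset:
    """A named experimental condition.

    ``joint_cells`` orders the bait-spot occupancy probabilities as
    ``(monomer & no partner, monomer & partner, dimer & no partner,
    dimer & partner)``.
    """

    name: str
    distance_params: tuple[float, float] | None = None   # (mean A, sd A)
    two_step_probability: float = 0.0
    joint_cells: tuple[float, float, float, float] | None = None
    background_coincidence: float = 0.08
    n_molecules_default: int = 16

    def __post_init__(self) -> None:
        if not 0.0 <= self.two_step_probability <= 1.0:
            raise ValueError("two_step_probability must be in [0, 1]")
        if self.joint_cells is not None:
            _validate_joint(self.joint_cells)

    @property
    def overall_interaction(self) -> float:
        """P(partner present) implied by the joint cells."""
        if self.joint_cells is None:
            raise ValueError(f"preset {self.name!r} has no joint cells")
        return self.joint_cells[1] + self.joint_cells[3]


def _solve_joint_from_conditionals(
    p_partner_given_mono: float,
    p_dimer_given_absent: float,
    p_partner_given_dimer: float,
) -> tuple[float, float, float, float]:
    """Solve the 2x2 joint from three conditional probabilities.

    With M the monomer marginal: mR = a*M, m0 = (1-a)*M, then
    d0 = b/(1-b) * m0 and dR = c/(1-c) * d0; M follows from normalization.
    """
    a, b, c = p_partner_given_mono, p_dimer_given_absent, p_partner_given_dimer
    m0_per_m = 1.0 - a
    d0_per_m = b / (1.0 - b) * m0_per_m
    dr_per_m = c / (1.0 - c) * d0_per_m
    m_total = 1.0 / (1.0 + d0_per_m + dr_per_m)
    cells = (
        m0_per_m * m_total,
        a * m_total,
        d0_per_m * m_total,
        dr_per_m * m_total,
    )
    s = sum(cells)
    return tuple(x / s for x in cells)  # type: ignore[return-value]


# Lit pull-down joint solved from the three measured conditionals:
# P(partner | monomer) = 0.251, P(dimer | no partner) = 0.155,
# P(partner | dimer) = 0.104; overall interaction comes out at ~23.1%.
_PULLDOWN_LIT_JOINT = _solve_joint_from_conditionals(0.251, 0.155, 0.104)

# The dark-condition colocalization level is not separately quantified in the
# system this emulates; 5% (background scale) is an assumption, combined with
# the measured dark dimer-without-partner fraction 6.1% and a partner-bound
# dimer rate at the 1-2% background level.
_PULLDOWN_DARK_JOINT = (
    0.95 - 0.061 * 0.95,       # monomer, no partner
    0.05 - 0.015 * 0.05,       # monomer, partner
    0.061 * 0.95,              # dimer, no partner
    0.015 * 0.05,              # dimer, partner
)

PRESETS: dict[str, ConditionPreset] = {
    "dark-monomer": ConditionPreset(
        name="dark-monomer",
        distance_params=(50.0, 13.0),
        two_step_probability=0.075,
        n_molecules_default=16,
    ),
    "lit-monomer": ConditionPreset(
        name="lit-monomer",
        distance_params=(65.0, 12.0),
        two_step_probability=0.251,
        n_molecules_default=22,
    ),
    "lit-dimer": ConditionPreset(
        name="lit-dimer",
        distance_params=(48.0, 12.0),
        two_step_probability=1.0,
        n_molecules_default=65,
    ),
    "pulldown-dark": ConditionPreset(
        name="pulldown-dark",
        joint_cells=tuple(
            np.asarray(_PULLDOWN_DARK_JOINT) / np.sum(_PULLDOWN_DARK_JOINT)
        ),
        n_molecules_default=2000,
    ),
    "pulldown-lit": ConditionPreset(
        name="pulldown-lit",
        joint_cells=_PULLDOWN_LIT_JOINT,
        n_molecules_default=2000,
    ),
}


def get_preset(name: str) -> ConditionPreset:
    try:
        return PRESETS[name]
    except KeyError:
        valid = ", ".join(sorted(PRESETS))
        raise KeyError(f"unknown preset {name!r}; valid presets: {valid}") from None


# --------------------------------------------------------------------------
# data containers
# --------------------------------------------------------------------------

@dataclass
class Trace:
    """One molecule's intensity time trace (two-channel or single-colour)."""

    time: np.ndarray                    # s, per frame
    donor: np.ndarray                   # counts / frame
    acceptor: np.ndarray | None = None  # counts / frame; None for single-colour
    truth: dict | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.donor = np.asarray(self.donor, dtype=float)
        if self.acceptor is not None:
            self.acceptor = np.asarray(self.acceptor, dtype=float)
            if self.acceptor.shape != self.donor.shape:
                raise ValueError("donor and acceptor must have equal length")
        if self.time.shape != self.donor.shape:
            raise ValueError("time and intensity arrays must have equal length")
        if not np.all(np.isfinite(self.donor)):
            raise ValueError("non-finite donor counts")

    @property
    def n_frames(self) -> int:
        return self.donor.size


@dataclass
class SpotField:
    """A pair of single-channel images of the same field of view."""

    green: np.ndarray
    red: np.ndarray
    truth: pd.DataFrame      # x_px, y_px, n_subunits, partner_present, molecule_id
    psf_sigma: float
    channel_offset: tuple[float, float]

    def __post_init__(self) -> None:
        if self.green.ndim != 2 or self.red.ndim != 2:
            raise ValueError("images must be 2-D")
        if np.any(self.green < 0) or np.any(self.red < 0):
            raise ValueError("intensities must be >= 0")


@dataclass
class TcspcHistogram:
    """Photon arrival-delay histogram (uniform bins)."""

    bin_edges: np.ndarray   # ns, length n_bins + 1
    counts: np.ndarray      # photons per bin
    truth_tau: float | None = None

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.counts = np.asarray(self.counts)
        widths = np.diff(self.bin_edges)
        if np.any(widths <= 0) or not np.allclose(widths, widths[0], rtol=1e-9):
            raise ValueError("bin widths must be uniform and > 0")
        if np.any(self.counts < 0):
            raise ValueError("counts must be >= 0")

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    @property
    def window(self) -> float:
        return float(self.bin_edges[-1] - self.bin_edges[0])


@dataclass
class ConditionDataset:
    """A batch of simulated molecules from one condition preset."""

    preset: ConditionPreset
    kind: str                            # "fret" | "bleach" | "pulldown"
    traces: list[Trace]
    group_labels: np.ndarray             # per molecule
    truth: pd.DataFrame                  # per-molecule records
    seed: int | None = None

    @property
    def n_molecules(self) -> int:
        return len(self.traces)


# --------------------------------------------------------------------------
# trace generators
# --------------------------------------------------------------------------

def fret_efficiency_of_distance(r: np.ndarray | float, r0: float) -> np.ndarray | float:
    """E = 1 / (1 + (r/R0)^6)."""
    return 1.0 / (1.0 + (np.asarray(r, dtype=float) / r0) ** 6)


def _draw_distances(rng: np.random.Generator, config: TraceConfig) -> np.ndarray:
    """Rejection-sample positive distances from N(state_mean, state_sd)."""
    n = 1 if config.distance_jitter_mode == "static-per-molecule" else config.n_frames
    if config.state_sd == 0:
        return np.full(n, config.state_mean)
    out = np.empty(n)
    filled = 0
    attempts = 0
    while filled < n:
        draw = rng.normal(config.state_mean, config.state_sd, size=n - filled)
        attempts += draw.size
        ok = draw[draw > 0]
        out[filled:filled + ok.size] = ok
        filled += ok.size
    if attempts > 0 and 1.0 - n / attempts > 0.01:
        warnings.warn(
            f"distance rejection rate {1.0 - n / attempts:.1%} exceeds 1%; "
            "state_mean/state_sd place substantial mass at r <= 0",
            stacklevel=3,
        )
    return out


def _bleach_frame(rng: np.random.Generator, rate: float, config: TraceConfig) -> int | None:
    """Frame index of a bleach event, or None if it falls beyond the trace."""
    if rate <= 0:
        return None
    t = rng.exponential(1.0 / rate)
    frame = int(t / config.frame_interval)
    return frame if frame < config.n_frames else None


def generate_fret_trace(config: TraceConfig, rng: np.random.Generator | None = None) -> Trace:
    """Simulate a two-channel donor/acceptor trace for one molecule.

    Pre-bleach, the expected donor signal is ``B * (1 - E)`` and the acceptor
    ``gamma * B * E``.  After the acceptor bleaches, all signal moves to the
    donor channel; after the donor bleaches, both channels fall to
    background.  Additive Gaussian noise of ``noise_sd`` is applied to each
    channel independently.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_frames
    r = _draw_distances(rng, config)
    fd = _bleach_frame(rng, config.donor_bleach_rate, config)
    fa = _bleach_frame(rng, config.acceptor_bleach_rate, config)

    e = fret_efficiency_of_distance(r, config.r0)
    e_frames = np.broadcast_to(e, (n,)).copy()

    donor = config.donor_brightness * (1.0 - e_frames)
    acceptor = config.gamma * config.donor_brightness * e_frames

    frames = np.arange(n)
    if fa is not None:
        post_a = frames >= fa
        if fd is None or fa <= fd:
            donor = np.where(post_a, config.donor_brightness, donor)
            acceptor = np.where(post_a, 0.0, acceptor)
    if fd is not None:
        post_d = frames >= fd
        donor = np.where(post_d, 0.0, donor)
        acceptor = np.where(post_d, 0.0, acceptor)

    donor = donor + config.background_mean
    acceptor = acceptor + config.background_mean
    if config.noise_sd > 0:
        donor = donor + rng.normal(0.0, config.noise_sd, size=n)
        acceptor = acceptor + rng.normal(0.0, config.noise_sd, size=n)

    truth = {
        "distance": float(r[0]) if r.size == 1 else r,
        "efficiency": float(e[0]) if np.ndim(e) and e.size == 1 else e,
        "donor_bleach_frame": fd,
        "acceptor_bleach_frame": fa,
    }
    time = frames * config.frame_interval
    return Trace(time=time, donor=donor, acceptor=acceptor, truth=truth)


def generate_bleach_trace(
    n_fluorophores: int,
    config: TraceConfig,
    rng: np.random.Generator | None = None,
) -> Trace:
    """Simulate a single-colour trace with ``n_fluorophores`` in {1, 2}.

    Each fluorophore contributes ``donor_brightness`` counts per frame until
    its exponential bleach time.  Bleach times landing in the same frame are
    resampled so the true step count is unambiguous.
    """
    if n_fluorophores not in (1, 2):
        raise ValueError("n_fluorophores must be 1 or 2")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_frames
    rate = config.donor_bleach_rate

    while True:
        frames_bleach = []
        times_bleach = []
        for _ in range(n_fluorophores):
            if rate <= 0:
                frames_bleach.append(None)
            else:
                t = rng.exponential(1.0 / rate)
                f = int(t / config.frame_interval)
                frames_bleach.append(f if f < n else None)
                times_bleach.append(t)
        concrete = [f for f in frames_bleach if f is not None]
        if len(set(concrete)) == len(concrete):
            break  # no same-frame ties

    signal = np.zeros(n)
    for f in frames_bleach:
        alive = np.ones(n) if f is None else (np.arange(n) < f).astype(float)
        signal += config.donor_brightness * alive
    signal += config.background_mean
    if config.noise_sd > 0:
        signal = signal + rng.normal(0.0, config.noise_sd, size=n)

    truth = {
        "n_fluorophores": n_fluorophores,
        "bleach_frames": sorted(concrete),
        "bleach_times_s": sorted(times_bleach),
        "n_bleached": len(concrete),
    }
    return Trace(time=np.arange(n) * config.frame_interval, donor=signal, truth=truth)


# --------------------------------------------------------------------------
# condition datasets
# --------------------------------------------------------------------------

def generate_condition_dataset(
    preset: ConditionPreset | str,
    n_molecules: int,
    seed: int | None = None,
    kind: str | None = None,
    config: TraceConfig | None = None,
    n_groups: int = 4,
) -> ConditionDataset:
    """Generate a batch of molecules under a condition preset.

    ``kind`` selects the output flavour: ``"fret"`` (two-channel traces with
    the preset's distance parameters), ``"bleach"`` (single-colour traces,
    each molecule two-step with probability ``two_step_probability``) or
    ``"pulldown"`` (single-colour traces whose (stoichiometry, partner)
    labels are drawn from the preset's joint cells).  Presets with joint
    cells default to ``"pulldown"``, others to ``"fret"``.

    Molecules are assigned round-robin to ``n_groups`` acquisition groups,
    mirroring the date-wise grouping used for group-wise SDs.
    """
    if isinstance(preset, str):
        preset = get_preset(preset)
    if n_molecules < 1:
        raise ValueError("n_molecules must be >= 1")
    if kind is None:
        kind = "pulldown" if preset.joint_cells is not None else "fret"
    if kind not in ("fret", "bleach", "pulldown"):
        raise ValueError("kind must be 'fret', 'bleach' or 'pulldown'")

    rng = np.random.default_rng(seed)
    group_labels = np.array(
        [f"group-{i % n_groups}" for i in range(n_molecules)], dtype=object
    )

    traces: list[Trace] = []
    records: list[dict] = []

    if kind == "fret":
        if preset.distance_params is None:
            raise ValueError(f"preset {preset.name!r} carries no distance parameters")
        mean, sd = preset.distance_params
        base = config or DEFAULT_FRET_CONFIG
        cfg = replace(base, state_mean=mean, state_sd=sd, seed=None)
        for i in range(n_molecules):
            tr = generate_fret_trace(cfg, rng=rng)
            traces.append(tr)
            records.append(
                {
                    "molecule_id": i,
                    "group": group_labels[i],
                    "true_distance": tr.truth["distance"],
                    "donor_bleach_frame": tr.truth["donor_bleach_frame"],
                    "acceptor_bleach_frame": tr.truth["acceptor_bleach_frame"],
                }
            )
    elif kind == "bleach":
        base = config or DEFAULT_BLEACH_CONFIG
        cfg = replace(base, seed=None)
        two_step = rng.random(n_molecules) < preset.two_step_probability
        for i in range(n_molecules):
            n_fl = 2 if two_step[i] else 1
            tr = generate_bleach_trace(n_fl, cfg, rng=rng)
            traces.append(tr)
            records.append(
                {
                    "molecule_id": i,
                    "group": group_labels[i],
                    "n_subunits": n_fl,
                    "bleach_frames": tr.truth["bleach_frames"],
                }
            )
    else:  # pulldown
        if preset.joint_cells is None:
            raise ValueError(f"preset {preset.name!r} carries no joint cells")
        base = config or DEFAULT_BLEACH_CONFIG
        cfg = replace(base, seed=None)
        cells = rng.choice(4, size=n_molecules, p=np.asarray(preset.joint_cells))
        n_subunits = np.where(cells >= 2, 2, 1)
        partner = np.isin(cells, (1, 3))
        for i in range(n_molecules):
            tr = generate_bleach_trace(int(n_subunits[i]), cfg, rng=rng)
            traces.append(tr)
            records.append(
                {
                    "molecule_id": i,
                    "group": group_labels[i],
                    "n_subunits": int(n_subunits[i]),
                    "partner_present": bool(partner[i]),
                    "bleach_frames": tr.truth["bleach_frames"],
                }
            )

    truth = pd.DataFrame.from_records(records)
    return ConditionDataset(
        preset=preset,
        kind=kind,
        traces=traces,
        group_labels=group_labels,
        truth=truth,
        seed=seed,
    )


# --------------------------------------------------------------------------
# spot images
# --------------------------------------------------------------------------

def _render_gaussians(
    shape: tuple[int, int],
    xs: np.ndarray,
    ys: np.ndarray,
    amps: np.ndarray,
    sigma: float,
) -> np.ndarray:
    """Sum of 2-D Gaussian PSFs on a pixel grid (amplitude = peak counts)."""
    img = np.zeros(shape, dtype=float)
    if xs.size == 0:
        return img
    half = max(3, int(np.ceil(4 * sigma)))
    h, w = shape
    for x, y, a in zip(xs, ys, amps):
        x0, x1 = int(np.floor(x)) - half, int(np.floor(x)) + half + 1
        y0, y1 = int(np.floor(y)) - half, int(np.floor(y)) + half + 1
        x0c, x1c = max(x0, 0), min(x1, w)
        y0c, y1c = max(y0, 0), min(y1, h)
        if x0c >= x1c or y0c >= y1c:
            continue
        gx = np.arange(x0c, x1c)
        gy = np.arange(y0c, y1c)
        g = np.exp(
            -((gy[:, None] - y) ** 2 + (gx[None, :] - x) ** 2) / (2 * sigma**2)
        )
        img[y0c:y1c, x0c:x1c] += a * g
    return img


def generate_spot_field(
    preset: ConditionPreset | str,
    image_shape: tuple[int, int] = (256, 256),
    density: float = 1.0e-3,
    seed: int | None = None,
    psf_sigma: float = 1.5,
    channel_offset: tuple[float, float] = (2.0, -1.0),
    amplitude: float = 300.0,
    background: float = 100.0,
    margin: float = 8.0,
) -> SpotField:
    """Render one two-channel field of view for a pull-down condition.

    Molecules are placed uniformly at random at the given mean density
    (spots per pixel^2); each bait molecule renders a Gaussian PSF in the
    green channel with amplitude proportional to its subunit count, and a
    partner-bound molecule additionally renders a prey PSF in the red
    channel, which is globally shifted by ``channel_offset`` (the dual-view
    splitter misalignment).  Both images carry Poisson shot noise on top of
    a constant background.
    """
    if isinstance(preset, str):
        preset = get_preset(preset)
    rng = np.random.default_rng(seed)
    h, w = image_shape
    area = (h - 2 * margin) * (w - 2 * margin)
    mean_spacing = 1.0 / np.sqrt(max(density, 1e-12))
    if density > 0 and mean_spacing <= 4 * psf_sigma:
        raise ValueError(
            f"density {density:g} too high: mean spacing {mean_spacing:.1f} px "
            f"<= 4 * psf_sigma = {4 * psf_sigma:.1f} px"
        )
    n_spots = rng.poisson(density * area)

    if preset.joint_cells is not None:
        cells = rng.choice(4, size=n_spots, p=np.asarray(preset.joint_cells))
        n_subunits = np.where(cells >= 2, 2, 1)
        partner = np.isin(cells, (1, 3))
    else:
        n_subunits = np.where(
            rng.random(n_spots) < preset.two_step_probability, 2, 1
        )
        partner = np.zeros(n_spots, dtype=bool)

    xs = rng.uniform(margin, w - margin, size=n_spots)
    ys = rng.uniform(margin, h - margin, size=n_spots)

    green = _render_gaussians(image_shape, xs, ys, amplitude * n_subunits, psf_sigma)
    dx, dy = channel_offset
    red = _render_gaussians(
        image_shape,
        xs[partner] + dx,
        ys[partner] + dy,
        np.full(int(partner.sum()), amplitude),
        psf_sigma,
    )
    green = rng.poisson(green + background).astype(float)
    red = rng.poisson(red + background).astype(float)

    truth = pd.DataFrame(
        {
            "x_px": xs,
            "y_px": ys,
            "n_subunits": n_subunits.astype(int),
            "partner_present": partner,
            "molecule_id": np.arange(n_spots),
        }
    )
    return SpotField(
        green=green,
        red=red,
        truth=truth,
        psf_sigma=psf_sigma,
        channel_offset=channel_offset,
    )


def render_spot_fields(
    dataset: ConditionDataset,
    image_shape: tuple[int, int] = (256, 256),
    spots_per_field: int = 200,
    seed: int | None = None,
    psf_sigma: float = 1.5,
    channel_offset: tuple[float, float] = (2.0, -1.0),
    amplitude: float = 300.0,
    background: float = 100.0,
    margin: float = 8.0,
) -> list[SpotField]:
    """Render a pull-down dataset's molecules into spot-image fields.

    The molecules of ``dataset`` (which carry stoichiometry, partner status
    and bleach traces) are partitioned into consecutive fields of
    ``spots_per_field`` each and placed at uniform random positions, so that
    image-based spot detection and pairing can be linked back to the per-
    molecule traces through the truth table's ``molecule_id``.
    """
    if dataset.kind != "pulldown":
        raise ValueError("render_spot_fields requires a pulldown dataset")
    rng = np.random.default_rng(seed)
    h, w = image_shape
    fields: list[SpotField] = []
    truth = dataset.truth
    for start in range(0, len(truth), spots_per_field):
        chunk = truth.iloc[start:start + spots_per_field]
        n = len(chunk)
        xs = rng.uniform(margin, w - margin, size=n)
        ys = rng.uniform(margin, h - margin, size=n)
        n_sub = chunk["n_subunits"].to_numpy()
        partner = chunk["partner_present"].to_numpy()
        green = _render_gaussians(image_shape, xs, ys, amplitude * n_sub, psf_sigma)
        dx, dy = channel_offset
        red = _render_gaussians(
            image_shape,
            xs[partner] + dx,
            ys[partner] + dy,
            np.full(int(partner.sum()), amplitude),
            psf_sigma,
        )
        green = rng.poisson(green + background).astype(float)
        red = rng.poisson(red + background).astype(float)
        ftruth = pd.DataFrame(
            {
                "x_px": xs,
                "y_px": ys,
                "n_subunits": n_sub.astype(int),
                "partner_present": partner,
                "molecule_id": chunk["molecule_id"].to_numpy(),
            }
        )
        fields.append(
            SpotField(
                green=green,
                red=red,
                truth=ftruth,
                psf_sigma=psf_sigma,
                channel_offset=channel_offset,
            )
        )
    return fields


# --------------------------------------------------------------------------
# TCSPC
# --------------------------------------------------------------------------

def generate_tcspc(
    tau: float,
    n_photons: int,
    bin_width: float = 0.05,
    window: float = 50.0,
    seed: int | None = None,
) -> TcspcHistogram:
    """Histogram of photon delays from a window-truncated Exponential(tau).

    Delays are drawn by inverse-CDF sampling of the exponential conditioned
    on the detection window, then binned on a uniform grid; ``tau``,
    ``bin_width`` and ``window`` are in nanoseconds.
    """
    if tau <= 0:
        raise ValueError("tau must be > 0")
    if window <= 0 or bin_width <= 0:
        raise ValueError("window and bin_width must be > 0")
    rng = np.random.default_rng(seed)
    n_bins = int(np.ceil(window / bin_width))
    edges = np.arange(n_bins + 1) * bin_width
    if n_photons == 0:
        return TcspcHistogram(bin_edges=edges, counts=np.zeros(n_bins, dtype=int),
                              truth_tau=tau)
    u = rng.random(n_photons)
    delays = -tau * np.log1p(-u * (1.0 - np.exp(-window / tau)))
    counts, _ = np.histogram(delays, bins=edges)
    return TcspcHistogram(bin_edges=edges, counts=counts, truth_tau=tau)


# --------------------------------------------------------------------------
# toy structures for scattering
# --------------------------------------------------------------------------

def sphere_points(
    radius: float,
    n_points: int = 1500,
    seed: int | None = 0,
):
    """Uniform unit-weight points filling a solid sphere (scattering toy body)."""
    from .saxs import CoordinateSet

    rng = np.random.default_rng(seed)
    pts = np.empty((0, 3))
    while pts.shape[0] < n_points:
        cand = rng.uniform(-radius, radius, size=(2 * n_points, 3))
        cand = cand[np.sum(cand**2, axis=1) <= radius**2]
        pts = np.vstack([pts, cand])
    pts = pts[:n_points]
    labels = [("A", i + 1, "CA") for i in range(n_points)]
    return CoordinateSet(points=pts, weights=np.ones(n_points), labels=labels)


def two_state_calpha_fixture(pair_distance: float, n_residues: int = 40, seed: int = 0):
    """Synthetic C-alpha chain whose first/last residues sit a set distance apart.

    A toy stand-in for a conformer model: a smooth 3-D random-walk-like
    backbone, rigidly rescaled so the labelled terminal residue pair is at
    ``pair_distance`` Angstrom.  Used to exercise inter-residue distance
    measurement (e.g., a compact ~45 A vs an extended ~62 A conformer).
    """
    from .saxs import CoordinateSet

    rng = np.random.default_rng(seed)
    steps = rng.normal(size=(n_residues - 1, 3))
    steps /= np.linalg.norm(steps, axis=1, keepdims=True)
    # bias the walk along +x so end-to-end distance is well-conditioned
    steps[:, 0] += 1.0
    steps *= 3.8 / np.linalg.norm(steps, axis=1, keepdims=True)
    pts = np.vstack([np.zeros(3), np.cumsum(steps, axis=0)])
    end_to_end = np.linalg.norm(pts[-1] - pts[0])
    pts = pts * (pair_distance / end_to_end)
    labels = [("A", i + 1, "CA") for i in range(n_residues)]
    return CoordinateSet(points=pts, weights=np.full(n_residues, 60.0), labels=labels)
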