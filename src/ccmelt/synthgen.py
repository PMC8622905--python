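"""Synthetic data generation: melting curves, coiled coils, trajectories.

These generators stand in for the CD spectropolarimeter and the MD engine
so that every analysis stage has a ground truth to be tested against:

* :func:`simulate_melt` draws two-state (van't Hoff) ellipticity-vs-
  temperature curves with sloping folded/unfolded baselines and seeded
  Gaussian noise;
* :func:`build_coiled_coil` places two-chain parallel coiled-coil backbones
  (N, CA, C) from the Crick parameterization - a superhelical CA trace with
  backbone atoms attached in local frames calibrated against an ideal
  alpha-helix, so the resulting phi/psi dihedrals are helical by
  construction;
* :func:`perturb_trajectory` turns one model into a frame series with a
  smooth global bend plus Gaussian fraying of the termini, emulating the
  end-to-end distance fluctuations of a long coiled coil in solution
  (a geometric, not physical, model);
* :func:`simulate_spectrum` mixes helix and coil basis spectra for
  round-trip tests of the single-wavelength helicity estimate.

All randomness flows from one explicit integer seed per call; the same
seed reproduces the same output bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cdmelt import (
    HelicityConstants,
    MeltingCurve,
    SpectrumRecord,
    two_state_signal,
)
from .errors import DomainError, GridError, ValidationError
from .seqcore import AMINO_ACIDS
from .trajgeom import Residue, StructureModel, TrajectoryFrames

# ---------------------------------------------------------------------------
# Two-state melting curves
# ---------------------------------------------------------------------------


def _default_grid() -> np.ndarray:
    # 0-90 degC at the instrument's typical 0.5 degC step
    return np.arange(0.0, 90.0 + 1e-9, 0.5)


@dataclass(frozen=True)
class TwoStateParams:
    """Parameters of a simulated two-state melting experiment.

    Defaults emulate a mid-stability coiled-coil fragment followed at
    222 nm: folded MRE near -30,000 deg cm^2 dmol^-1 with a gentle positive
    slope, unfolded near -3,000 with a slight negative slope, measured
    every 0.5 degC from 0 to 90 degC with ~1% of the signal range as
    Gaussian noise.
    """

    tm_true: float = 50.0  # degC
    dh_vh: float = 400.0  # kJ/mol
    folded_baseline: tuple[float, float] = (-30000.0, 30.0)
    unfolded_baseline: tuple[float, float] = (-3000.0, -10.0)
    noise_sd: float = 270.0  # deg cm^2 dmol^-1
    temperature_grid: np.ndarray = field(default_factory=_default_grid)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dh_vh <= 0:
            raise ValidationError("dh_vh must be > 0")
        grid = np.asarray(self.temperature_grid, dtype=float)
        object.__setattr__(self, "temperature_grid", grid)
        if grid.size >= 2 and not np.all(np.diff(grid) > 0):
            raise GridError("temperature grid must strictly increase")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")


def simulate_melt(
    params: TwoStateParams,
    sample_id: str = "synthetic",
    condition: str = "non_reduced",
    replicate_id: str = "1",
) -> MeltingCurve:
    """Simulate a noisy two-state melting curve.

    The pre-noise signal is ``(1 - f_U) folded(T) + f_U unfolded(T)`` with
    ``f_U = K / (1 + K)`` and ``K = exp(-(dH/R)(1/T - 1/Tm))``; at
    ``T = tm_true`` the fraction unfolded is exactly one half.
    """
    grid = params.temperature_grid
    if grid.size < 10:
        raise GridError(f"grid must have >= 10 points, got {grid.size}")
    signal = two_state_signal(
        grid,
        params.tm_true,
        params.dh_vh,
        params.folded_baseline,
        params.unfolded_baseline,
    )
    rng = np.random.default_rng(params.seed)
    signal = signal + rng.normal(0.0, params.noise_sd, grid.size)
    return MeltingCurve(grid.copy(), signal, sample_id, condition, replicate_id)


# ---------------------------------------------------------------------------
# Crick-parameterized coiled coils
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CrickParams:
    """Crick parameterization of a parallel two-chain coiled coil.

    Defaults are canonical dimeric values: superhelix radius R0 = 4.9 A,
    alpha-helix (minor) radius R1 = 2.26 A, axial rise 1.495 A/residue, a
    left-handed superhelix of ~140 A pitch, and a minor-helix frequency of
    +102.86 deg/residue (720/7, so the heptad phase repeats exactly and
    the *a*/*d* positions keep facing the partner chain). ``phi1`` rotates
    the minor-helix phase; the default points residue 0 at the partner.
    """

    superhelix_radius: float = 4.9  # R0, Angstrom
    helix_radius: float = 2.26  # R1, Angstrom
    rise_per_residue: float = 1.495  # Angstrom along the superhelix axis
    pitch: float = 140.0  # superhelix pitch, Angstrom (left-handed)
    omega1: float = np.radians(720.0 / 7.0)  # rad/residue, minor helix
    phi1: float = np.pi  # rad, minor-helix phase at residue 0
    n_residues: int = 98

    def __post_init__(self) -> None:
        if self.superhelix_radius <= 0 or self.helix_radius <= 0:
            raise ValidationError("radii must be > 0")
        if self.n_residues < 7:
            raise ValidationError("n_residues must be >= 7")

    @property
    def omega0(self) -> float:
        """Superhelical frequency (rad/residue); negative = left-handed."""
        return -2.0 * np.pi * self.rise_per_residue / self.pitch


# Ideal alpha-helix dihedrals used to calibrate backbone placement.
HELIX_PHI = -60.0
HELIX_PSI = -47.0

_BOND_N_CA = 1.458
_BOND_CA_C = 1.525
_BOND_C_N = 1.329
_ANGLE_N_CA_C = 111.2
_ANGLE_CA_C_N = 116.2
_ANGLE_C_N_CA = 121.7


def _place_atom(a, b, c, bond: float, angle_deg: float, dihedral_deg: float):
    """Natural-extension-reference-frame placement of one atom.

    Returns the point at the given bond length from ``c``, bond angle with
    ``b``-``c``, and dihedral ``a``-``b``-``c``-new.
    """
    angle = np.radians(angle_deg)
    dihedral = np.radians(dihedral_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array(
        [
            -bond * np.cos(angle),
            bond * np.sin(angle) * np.cos(dihedral),
            bond * np.sin(angle) * np.sin(dihedral),
        ]
    )
    return c + d[0] * bc + d[1] * m + d[2] * n


def backbone_from_dihedrals(
    phi_psi: list[tuple[float, float]], omega: float = 180.0
) -> list[dict[str, np.ndarray]]:
    """Build an N/CA/C backbone from per-residue (phi, psi) in degrees.

    Residue ``i`` gets exactly the requested ``phi[i]`` (ignored for the
    first residue, where it is undefined) and ``psi[i]`` (undefined for
    the last residue but still used to seed the construction). Standard
    bond lengths and angles are used throughout.
    """
    n = len(phi_psi)
    if n < 2:
        raise ValidationError("need at least two residues")
    first_n = np.array([0.0, 0.0, 0.0])
    first_ca = np.array([_BOND_N_CA, 0.0, 0.0])
    ang = np.radians(180.0 - _ANGLE_N_CA_C)
    first_c = first_ca + _BOND_CA_C * np.array([np.cos(ang), np.sin(ang), 0.0])
    atoms = [{"N": first_n, "CA": first_ca, "C": first_c}]
    for i in range(1, n):
        prev = atoms[-1]
        psi_prev = phi_psi[i - 1][1]
        n_i = _place_atom(
            prev["N"], prev["CA"], prev["C"], _BOND_C_N, _ANGLE_CA_C_N, psi_prev
        )
        ca_i = _place_atom(prev["CA"], prev["C"], n_i, _BOND_N_CA, _ANGLE_C_N_CA, omega)
        c_i = _place_atom(prev["C"], n_i, ca_i, _BOND_CA_C, _ANGLE_N_CA_C, phi_psi[i][0])
        atoms.append({"N": n_i, "CA": ca_i, "C": c_i})
    return atoms


def _ca_frame(prev_ca, ca, next_ca) -> np.ndarray:
    """Orthonormal local frame (rows) at a CA from its trace neighbours."""
    u = next_ca - ca
    v = prev_ca - ca
    e1 = u + v
    e1 = e1 / np.linalg.norm(e1)
    e2 = u - v
    e2 = e2 - np.dot(e2, e1) * e1
    e2 = e2 / np.linalg.norm(e2)
    e3 = np.cross(e1, e2)
    return np.vstack([e1, e2, e3])


def _backbone_offsets() -> tuple[np.ndarray, np.ndarray]:
    """N and C offsets, in the local CA frame, of an ideal alpha-helix."""
    n = 21
    ideal = backbone_from_dihedrals([(HELIX_PHI, HELIX_PSI)] * n)
    cas = [a["CA"] for a in ideal]
    i = n // 2
    frame = _ca_frame(cas[i - 1], cas[i], cas[i + 1])
    n_off = frame @ (ideal[i]["N"] - cas[i])
    c_off = frame @ (ideal[i]["C"] - cas[i])
    return n_off, c_off


def _crick_ca_trace(cp: CrickParams, indices: np.ndarray) -> np.ndarray:
    """CA coordinates of chain A for (possibly fractional) residue indices."""
    t = np.asarray(indices, dtype=float)
    w0 = cp.omega0
    theta = w0 * t
    axis = np.stack(
        [
            cp.superhelix_radius * np.cos(theta),
            cp.superhelix_radius * np.sin(theta),
            cp.rise_per_residue * t,
        ],
        axis=1,
    )
    tangent = np.stack(
        [
            -cp.superhelix_radius * w0 * np.sin(theta),
            cp.superhelix_radius * w0 * np.cos(theta),
            np.full_like(theta, cp.rise_per_residue),
        ],
        axis=1,
    )
    tangent = tangent / np.linalg.norm(tangent, axis=1)[:, None]
    outward = np.stack([np.cos(theta), np.sin(theta), np.zeros_like(theta)], axis=1)
    binormal = np.cross(tangent, outward)
    phase = cp.phi1 + cp.omega1 * t
    return axis + cp.helix_radius * (
        np.cos(phase)[:, None] * outward + np.sin(phase)[:, None] * binormal
    )


def build_coiled_coil(
    sequence: str,
    cp: CrickParams | None = None,
    first_position: int = 1,
    chain_ids: tuple[str, str] = ("A", "B"),
) -> StructureModel:
    """Build a parallel two-chain coiled-coil backbone from a sequence.

    Chain A follows the Crick CA trace; backbone N and C atoms are placed
    in local frames derived from the trace, with offsets calibrated
    against an ideal alpha-helix so every residue's phi/psi falls in the
    helical region. Chain B is the C2-symmetric partner (180 degree
    rotation about the superhelix axis), giving a parallel dimer whose
    equivalent residues sit ~2 R0 apart. Residues are numbered from
    ``first_position``.
    """
    cp = cp or CrickParams(n_residues=len(sequence))
    if len(sequence) != cp.n_residues:
        raise ValidationError(
            f"sequence length {len(sequence)} != n_residues {cp.n_residues}"
        )
    bad = set(sequence.upper()) - AMINO_ACIDS
    if bad:
        raise ValidationError(f"non-standard residues in sequence: {sorted(bad)}")

    n = cp.n_residues
    # extend the trace by one virtual residue at each end so every real
    # residue has a proper local frame
    trace = _crick_ca_trace(cp, np.arange(-1, n + 1))
    n_off, c_off = _backbone_offsets()

    chain_a: list[Residue] = []
    for i in range(n):
        ca = trace[i + 1]
        frame = _ca_frame(trace[i], ca, trace[i + 2])
        atoms = {
            "N": ca + frame.T @ n_off,
            "CA": ca.copy(),
            "C": ca + frame.T @ c_off,
        }
        chain_a.append(Residue(first_position + i, sequence[i].upper(), atoms))

    # C2 rotation about the superhelix (z) axis: (x, y, z) -> (-x, -y, z)
    flip = np.array([-1.0, -1.0, 1.0])
    chain_b = [
        Residue(r.position, r.amino_acid, {k: v * flip for k, v in r.atoms.items()})
        for r in chain_a
    ]
    return StructureModel({chain_ids[0]: chain_a, chain_ids[1]: chain_b})


# ---------------------------------------------------------------------------
# Trajectory perturbation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PerturbationParams:
    """Frame-to-frame perturbation of a coiled-coil model.

    Each frame applies a smooth global bend about a random transverse axis
    (bend angle ~ |N(0, bend_amplitude)| radians over the molecule length)
    plus independent Gaussian displacement of the ``fray_length`` terminal
    residues, ramping up to ``fray_amplitude`` (A, 1 sd) at the chain
    ends. Defaults emulate a 200 ns run sampled every 0.4 ns.
    """

    n_frames: int = 500
    bend_amplitude: float = 0.15  # radians
    fray_length: int = 5  # residues per terminus
    fray_amplitude: float = 1.5  # Angstrom
    frame_interval_ns: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValidationError("n_frames must be >= 1")
        if self.bend_amplitude < 0 or self.fray_amplitude < 0:
            raise ValidationError("amplitudes must be >= 0")
        if self.fray_length < 0:
            raise ValidationError("fray_length must be >= 0")


def _bend_coordinates(coords: np.ndarray, azimuth: float, angle: float) -> np.ndarray:
    """Bend a z-elongated point cloud onto a circular arc.

    The bend happens in the plane spanned by z and the transverse
    direction given by ``azimuth``; ``angle`` is the total arc angle
    subtended by the molecule's z-extent. The axial fibre through the
    molecule centre keeps its length, so the end-to-end chord shortens as
    the chord of the arc.
    """
    if angle == 0.0:
        return coords.copy()
    z = coords[:, 2]
    z_mid = 0.5 * (z.min() + z.max())
    length = z.max() - z.min()
    radius = length / angle
    cos_b, sin_b = np.cos(azimuth), np.sin(azimuth)
    # rotate so the bend plane is the (x', z) plane
    xp = coords[:, 0] * cos_b + coords[:, 1] * sin_b
    yp = -coords[:, 0] * sin_b + coords[:, 1] * cos_b
    alpha = (z - z_mid) / radius
    new_xp = radius - (radius - xp) * np.cos(alpha)
    new_z = z_mid + (radius - xp) * np.sin(alpha)
    out = np.empty_like(coords)
    out[:, 0] = new_xp * cos_b - yp * sin_b
    out[:, 1] = new_xp * sin_b + yp * cos_b
    out[:, 2] = new_z
    return out


def perturb_trajectory(
    model: StructureModel, pp: PerturbationParams
) -> TrajectoryFrames:
    """Generate seeded trajectory frames from one model.

    Frame 0 is the unperturbed input. Later frames bend the whole molecule
    and displace terminal residues rigidly (all atoms of a residue move
    together, preserving its internal geometry). The same seed reproduces
    the same frames; because the random draws are scaled by the
    amplitudes, trajectories generated with the same seed and increasing
    ``bend_amplitude`` bend progressively more frame by frame.
    """
    rng = np.random.default_rng(pp.seed)
    chain_ids = model.chain_ids
    frames = [model.copy()]
    for _ in range(1, pp.n_frames):
        azimuth = rng.uniform(0.0, 2.0 * np.pi)
        angle = abs(rng.normal()) * pp.bend_amplitude

        new_model = model.copy()
        # flatten atoms, bend, write back
        all_xyz = []
        index = []
        for cid in chain_ids:
            for r_i, residue in enumerate(new_model.chains[cid]):
                for name, xyz in residue.atoms.items():
                    index.append((cid, r_i, name))
                    all_xyz.append(xyz)
        bent = _bend_coordinates(np.array(all_xyz), azimuth, angle)
        for (cid, r_i, name), xyz in zip(index, bent):
            new_model.chains[cid][r_i].atoms[name] = xyz

        # terminal fraying: rigid Gaussian displacement per residue,
        # ramping toward the chain ends
        for cid in chain_ids:
            residues = new_model.chains[cid]
            n_res = len(residues)
            for j in range(pp.fray_length):
                ramp = (pp.fray_length - j) / pp.fray_length
                for r_i in {j, n_res - 1 - j}:
                    shift = rng.normal(0.0, 1.0, 3) * pp.fray_amplitude * ramp
                    for name in residues[r_i].atoms:
                        residues[r_i].atoms[name] = residues[r_i].atoms[name] + shift
        frames.append(new_model)
    times = np.arange(pp.n_frames) * pp.frame_interval_ns
    return TrajectoryFrames(frames, times)


# ---------------------------------------------------------------------------
# CD spectra
# ---------------------------------------------------------------------------


def _gaussian(x, centre, width):
    return np.exp(-(((x - centre) / width) ** 2))


def simulate_spectrum(
    helix_fraction: float,
    wavelengths,
    n_residues: int = 98,
    temperature: float = 0.0,
    constants: HelicityConstants | None = None,
    sample_id: str = "synthetic",
    condition: str = "non_reduced",
) -> SpectrumRecord:
    """Linear helix/coil basis combination of a far-UV CD spectrum.

    The helix basis has the characteristic double minimum near 208 and
    222 nm and a positive band near 193 nm, scaled so its value at 222 nm
    equals the chain-length-corrected helix limit of ``constants``; the
    coil basis has a single negative band near 198 nm and equals the coil
    baseline at 222 nm. Feeding the 222 nm value of a simulated spectrum
    back into the helicity estimate therefore recovers ``helix_fraction``.
    """
    if not 0.0 <= helix_fraction <= 1.0:
        raise DomainError("helix_fraction must lie in [0, 1]")
    w = np.asarray(wavelengths, dtype=float)
    c = constants or HelicityConstants()

    helix_222 = c.helix_limit(n_residues)
    shape = (
        _gaussian(w, 222.0, 10.5)
        + 0.95 * _gaussian(w, 208.0, 9.0)
        - 1.30 * _gaussian(w, 193.0, 8.0)
    )
    shape_at_222 = (
        _gaussian(222.0, 222.0, 10.5)
        + 0.95 * _gaussian(222.0, 208.0, 9.0)
        - 1.30 * _gaussian(222.0, 193.0, 8.0)
    )
    helix_basis = helix_222 * shape / shape_at_222

    coil_222 = c.coil_limit(temperature)
    coil_band = _gaussian(w, 198.0, 9.0) - _gaussian(222.0, 198.0, 9.0)
    coil_basis = coil_222 + (-20000.0 - coil_222) * coil_band / (
        1.0 - _gaussian(222.0, 198.0, 9.0)
    )

    mre = helix_fraction * helix_basis + (1.0 - helix_fraction) * coil_basis
    return SpectrumRecord(w, mre, temperature, condition, sample_id)
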