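"""Geometry analysis of coiled-coil coordinate frames.

Works on light-weight structure models (chains of residues with named
atoms; backbone N, CA, C are enough) rather than full topologies, because
the quantities of interest are purely geometric:

* helix-boundary detection from backbone phi/psi dihedrals, excluding
  frayed/disordered termini so that only the coiled-coil part is measured;
* the per-chain end-to-end CA-CA distance between the first and last
  helix-forming residues, tracked across trajectory frames as a proxy for
  molecular bending;
* summary statistics (mean +/- sd per chain, and the fragment average over
  chains) formatted the way such distances are conventionally reported,
  e.g. ``78.24 +/- 6.23 A``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.PDB.vectors import Vector, calc_dihedral

from .errors import (
    AlignmentError,
    AtomError,
    ParameterError,
    PositionError,
    ValidationError,
)

#: Dihedral windows (degrees) inside which a residue counts as alpha-helical.
PHI_WINDOW = (-100.0, -30.0)
PSI_WINDOW = (-80.0, -5.0)


@dataclass
class Residue:
    """One residue: native position, one-letter code, named atoms (A)."""

    position: int
    amino_acid: str
    atoms: dict[str, np.ndarray]

    def atom(self, name: str) -> np.ndarray:
        try:
            return self.atoms[name]
        except KeyError:
            raise AtomError(
                f"residue {self.amino_acid}{self.position} has no atom {name!r}"
            ) from None

    def has(self, name: str) -> bool:
        return name in self.atoms


@dataclass
class StructureModel:
    """Chains of residues with coordinates in Angstrom.

    ``chains`` maps a chain id (e.g. ``"A"``, ``"B"``) to an ordered
    residue list with strictly increasing native positions.
    """

    chains: dict[str, list[Residue]]

    def __post_init__(self) -> None:
        for cid, residues in self.chains.items():
            positions = [r.position for r in residues]
            if any(b <= a for a, b in zip(positions, positions[1:])):
                raise ValidationError(f"chain {cid}: positions must increase")

    @property
    def chain_ids(self) -> list[str]:
        return list(self.chains)

    def chain(self, chain_id: str) -> list[Residue]:
        try:
            return self.chains[chain_id]
        except KeyError:
            raise ValidationError(f"no chain {chain_id!r} in model") from None

    def residue(self, chain_id: str, position: int) -> Residue:
        for r in self.chain(chain_id):
            if r.position == position:
                return r
        raise PositionError(f"chain {chain_id}: no residue at position {position}")

    def ca_positions(self, chain_id: str) -> tuple[np.ndarray, np.ndarray]:
        """(native positions, CA coordinates) for one chain."""
        residues = self.chain(chain_id)
        pos = np.array([r.position for r in residues])
        coords = np.array([r.atom("CA") for r in residues])
        return pos, coords

    def topology_key(self) -> tuple:
        return tuple(
            (cid, tuple((r.position, r.amino_acid) for r in residues))
            for cid, residues in self.chains.items()
        )

    def copy(self) -> "StructureModel":
        return StructureModel(
            {
                cid: [
                    Residue(
                        r.position,
                        r.amino_acid,
                        {n: xyz.copy() for n, xyz in r.atoms.items()},
                    )
                    for r in residues
                ]
                for cid, residues in self.chains.items()
            }
        )


@dataclass
class TrajectoryFrames:
    """An ordered sequence of structure models sharing one topology."""

    frames: list[StructureModel]
    frame_times: np.ndarray  # ns

    def __post_init__(self) -> None:
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if len(self.frames) != self.frame_times.size:
            raise ValidationError("frames and frame_times differ in length")
        if np.any(np.diff(self.frame_times) < 0):
            raise ValidationError("frame times must be non-decreasing")
        if self.frames:
            key = self.frames[0].topology_key()
            for i, f in enumerate(self.frames[1:], start=1):
                if f.topology_key() != key:
                    raise ValidationError(f"frame {i} has a different topology")

    @property
    def n_frames(self) -> int:
        return len(self.frames)


@dataclass(frozen=True)
class HelixSpan:
    """First and last helix-forming residues of one chain."""

    chain: str
    first_helical_residue: int
    last_helical_residue: int

    def __post_init__(self) -> None:
        if self.first_helical_residue >= self.last_helical_residue:
            raise ValidationError("helix span must contain at least two residues")


@dataclass
class DistanceSeries:
    """End-to-end CA-CA distance of one chain across frames."""

    chain: str
    times: np.ndarray  # ns
    distances: np.ndarray  # Angstrom

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.distances = np.asarray(self.distances, dtype=float)
        if self.times.shape != self.distances.shape:
            raise ValidationError("times and distances differ in length")
        if np.any(self.distances < 0):
            raise ValidationError("distances must be non-negative")

    def mean(self) -> float:
        return float(self.distances.mean())

    def sd(self, ddof: int = 0) -> float:
        """Standard deviation over frames (population by default)."""
        return float(self.distances.std(ddof=ddof))

    def formatted(self, ddof: int = 0) -> str:
        return f"{self.mean():.2f} +/- {self.sd(ddof):.2f} A"


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def backbone_dihedrals(
    model: StructureModel, chain: str
) -> list[tuple[int, float | None, float | None]]:
    """Per-residue (position, phi, psi) in degrees; None where undefined.

    phi needs the preceding residue's C, psi the following residue's N, so
    the chain termini each have one undefined dihedral. Dihedrals are only
    computed between residues at consecutive native positions.
    """
    residues = model.chain(chain)
    out = []
    for i, r in enumerate(residues):
        for name in ("N", "CA", "C"):
            r.atom(name)  # AtomError if missing
        prev_r = residues[i - 1] if i > 0 else None
        next_r = residues[i + 1] if i + 1 < len(residues) else None
        phi = psi = None
        if prev_r is not None and prev_r.position == r.position - 1:
            phi = _dihedral_deg(
                prev_r.atom("C"), r.atom("N"), r.atom("CA"), r.atom("C")
            )
        if next_r is not None and next_r.position == r.position + 1:
            psi = _dihedral_deg(
                r.atom("N"), r.atom("CA"), r.atom("C"), next_r.atom("N")
            )
        out.append((r.position, phi, psi))
    return out


def _dihedral_deg(p0, p1, p2, p3) -> float:
    return float(
        np.degrees(calc_dihedral(Vector(*p0), Vector(*p1), Vector(*p2), Vector(*p3)))
    )


def helix_span(
    model: StructureModel,
    chain: str,
    min_run: int = 4,
    phi_window: tuple[float, float] = PHI_WINDOW,
    psi_window: tuple[float, float] = PSI_WINDOW,
) -> HelixSpan | None:
    """Span from the first to the last residue of a helical run.

    A residue is helical when every dihedral it defines (phi, psi, or both)
    falls inside the corresponding window; a run must contain at least
    ``min_run`` consecutive residues to count, which filters the short
    helical stretches that survive in otherwise frayed termini. Returns
    ``None`` when no qualifying run exists (a no-helix result, distinct
    from an error).
    """
    if min_run < 1:
        raise ParameterError("min_run must be >= 1")
    helical = []
    for position, phi, psi in backbone_dihedrals(model, chain):
        ok = True
        defined = 0
        if phi is not None:
            defined += 1
            ok &= phi_window[0] <= phi <= phi_window[1]
        if psi is not None:
            defined += 1
            ok &= psi_window[0] <= psi <= psi_window[1]
        helical.append((position, ok and defined > 0))

    runs: list[tuple[int, int]] = []
    start = prev = None
    for position, is_hel in helical:
        if is_hel and start is None:
            start = prev = position
        elif is_hel and position == prev + 1:
            prev = position
        elif is_hel:  # helical but after a positional gap
            runs.append((start, prev))
            start = prev = position
        elif start is not None:
            runs.append((start, prev))
            start = prev = None
    if start is not None:
        runs.append((start, prev))

    runs = [(a, b) for a, b in runs if b - a + 1 >= min_run]
    if not runs:
        return None
    return HelixSpan(chain, runs[0][0], runs[-1][1])


def end_to_end(
    frames: TrajectoryFrames, chain: str, first: int, last: int
) -> DistanceSeries:
    """Per-frame Euclidean CA-CA distance between two residues.

    Symmetric in ``first``/``last``; raises :class:`AtomError` naming the
    frame if either CA is missing anywhere in the trajectory.
    """
    distances = np.empty(frames.n_frames)
    for i, model in enumerate(frames.frames):
        try:
            a = model.residue(chain, first).atom("CA")
            b = model.residue(chain, last).atom("CA")
        except AtomError as exc:
            raise AtomError(f"frame {i}: {exc}") from None
        distances[i] = np.linalg.norm(a - b)
    return DistanceSeries(chain, frames.frame_times.copy(), distances)


def summarize_series(
    series: list[DistanceSeries], ddof: int = 0
) -> pd.DataFrame:
    """Per-chain and fragment-average distance statistics.

    Per chain: mean +/- sd over frames. The fragment average first takes
    the per-frame mean across chains, then the mean +/- sd of that series
    over frames; with equal chains this reduces to the chain values. The
    ``formatted`` column renders ``mean +/- sd A`` at 0.01 A.
    """
    if not series:
        raise ValidationError("no distance series to summarize")
    rows = []
    for s in series:
        rows.append(
            {
                "chain": s.chain,
                "n_frames": int(s.distances.size),
                "mean_A": round(s.mean(), 2),
                "sd_A": round(s.sd(ddof), 2),
                "formatted": s.formatted(ddof),
            }
        )
    n0 = series[0].distances.size
    if any(s.distances.size != n0 for s in series):
        raise AlignmentError("chain averaging requires equal frame counts")
    stacked = np.vstack([s.distances for s in series])
    per_frame_mean = stacked.mean(axis=0)
    avg = DistanceSeries("average", series[0].times.copy(), per_frame_mean)
    rows.append(
        {
            "chain": "average",
            "n_frames": n0,
            "mean_A": round(avg.mean(), 2),
            "sd_A": round(avg.sd(ddof), 2),
            "formatted": avg.formatted(ddof),
        }
    )
    return pd.DataFrame(rows)
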