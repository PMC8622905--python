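"""File formats: FASTA, melting/spectrum CSV dialects, multi-model PDB, TSV.

Dialects
--------
* FASTA headers carry the isoform id plus ``start=<pos>`` (and optionally
  ``offset=<int>``) tokens, e.g. ``>Tpm1.1 start=64 offset=0``.
* Melting CSV: ``temperature_C,signal,sample_id,condition,replicate`` -
  one curve per (sample_id, condition, replicate) group, temperatures
  sorted ascending on read.
* Spectrum CSV: ``wavelength_nm,mre,sample_id,condition``.
* Trajectories travel as multi-model PDB (MODEL/ENDMDL records, fixed
  columns, chain ids, 1-based native residue numbers, coordinates in A);
  frame times in ns are stored on a ``REMARK 100 TIME_NS`` line per model.

Numbers use a decimal point only; every writer/reader pair round-trips its
dialect exactly (coordinates at the PDB's 3-decimal precision).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio.SeqUtils import seq1 as _seq1
from Bio.SeqUtils import seq3 as _seq3

from .cdmelt import MeltingCurve, MeltingResult, SpectrumRecord
from .errors import AlphabetError, FormatError
from .seqcore import AMINO_ACIDS, IsoformSequence
from .trajgeom import Residue, StructureModel, TrajectoryFrames

MELTING_CSV_COLUMNS = ["temperature_C", "signal", "sample_id", "condition", "replicate"]
SPECTRUM_CSV_COLUMNS = ["wavelength_nm", "mre", "sample_id", "condition"]


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path) -> list[IsoformSequence]:
    """Read sequences with native numbering from FASTA.

    The record id is the isoform id; a ``start=<int>`` token in the
    description sets the first native position (default 1) and
    ``offset=<int>`` the numbering offset.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    sequences = []
    for rec in records:
        start, offset = 1, 0
        for token in rec.description.split()[1:]:
            if token.startswith("start="):
                start = int(token[6:])
            elif token.startswith("offset="):
                offset = int(token[7:])
        seq = str(rec.seq).upper()
        for i, aa in enumerate(seq):
            if aa not in AMINO_ACIDS:
                raise AlphabetError(
                    f"{path}: record {rec.id!r} has illegal residue {aa!r} "
                    f"at sequence position {i + 1}"
                )
        sequences.append(
            IsoformSequence.from_string(rec.id, seq, start, offset)
        )
    return sequences


def write_fasta(sequences: list[IsoformSequence], path) -> None:
    records = [
        SeqRecord(
            Seq(s.sequence),
            id=s.isoform_id,
            description=(
                f"{s.isoform_id} start={s.first_position} "
                f"offset={s.numbering_offset}"
            ),
        )
        for s in sequences
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Melting / spectrum CSV
# ---------------------------------------------------------------------------


def read_melting_csv(path) -> list[MeltingCurve]:
    """Read melting curves; one per (sample_id, condition, replicate)."""
    try:
        frame = pd.read_csv(path, dtype={"replicate": str})
    except Exception as exc:  # noqa: BLE001 - surface as dialect error
        raise FormatError(f"{path}: cannot parse CSV: {exc}") from exc
    missing = [c for c in MELTING_CSV_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    if not pd.api.types.is_numeric_dtype(frame["temperature_C"]):
        raise FormatError(f"{path}: non-numeric temperature_C values")
    if not pd.api.types.is_numeric_dtype(frame["signal"]):
        raise FormatError(f"{path}: non-numeric signal values")
    dup = frame.duplicated(
        subset=["sample_id", "condition", "replicate", "temperature_C"]
    )
    if dup.any():
        row = frame[dup].iloc[0]
        raise FormatError(
            f"{path}: duplicated point (sample {row['sample_id']!r}, "
            f"{row['condition']}, replicate {row['replicate']}, "
            f"T={row['temperature_C']})"
        )
    curves = []
    for (sample, condition, replicate), group in frame.groupby(
        ["sample_id", "condition", "replicate"], sort=True
    ):
        ordered = group.sort_values("temperature_C")
        curves.append(
            MeltingCurve(
                ordered["temperature_C"].to_numpy(float),
                ordered["signal"].to_numpy(float),
                sample_id=str(sample),
                condition=str(condition),
                replicate_id=str(replicate),
            )
        )
    return curves


def write_melting_csv(curves: list[MeltingCurve], path) -> None:
    rows = []
    for c in curves:
        for t, x in zip(c.temperatures, c.signal):
            rows.append(
                {
                    "temperature_C": t,
                    "signal": x,
                    "sample_id": c.sample_id,
                    "condition": c.condition,
                    "replicate": c.replicate_id,
                }
            )
    pd.DataFrame(rows, columns=MELTING_CSV_COLUMNS).to_csv(path, index=False)


def read_spectrum_csv(path) -> list[SpectrumRecord]:
    frame = pd.read_csv(path)
    missing = [c for c in SPECTRUM_CSV_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    records = []
    for (sample, condition), group in frame.groupby(
        ["sample_id", "condition"], sort=True
    ):
        ordered = group.sort_values("wavelength_nm")
        records.append(
            SpectrumRecord(
                ordered["wavelength_nm"].to_numpy(float),
                ordered["mre"].to_numpy(float),
                condition=str(condition),
                sample_id=str(sample),
            )
        )
    return records


def write_spectrum_csv(records: list[SpectrumRecord], path) -> None:
    rows = []
    for r in records:
        for w, m in zip(r.wavelengths, r.mre):
            rows.append(
                {
                    "wavelength_nm": w,
                    "mre": m,
                    "sample_id": r.sample_id,
                    "condition": r.condition,
                }
            )
    pd.DataFrame(rows, columns=SPECTRUM_CSV_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Multi-model PDB
# ---------------------------------------------------------------------------

_ELEMENT = {"N": "N", "CA": "C", "C": "C", "O": "O", "CB": "C"}


def _atom_line(
    serial: int, name: str, res3: str, chain: str, resseq: int, xyz
) -> str:
    # PDB v3.3 fixed columns; atom names of <4 chars start in column 14
    padded = f" {name:<3s}" if len(name) < 4 else name
    return (
        f"ATOM  {serial:5d} {padded}{'':1s}{res3:>3s} {chain:1s}"
        f"{resseq:4d}    {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
        f"{1.00:6.2f}{0.00:6.2f}          {_ELEMENT.get(name, name[0]):>2s}\n"
    )


def write_pdb(structure, path, frame_times=None) -> None:
    """Write a model or trajectory as (multi-model) PDB.

    ``structure`` is a :class:`StructureModel` or
    :class:`TrajectoryFrames`; frame times (ns) go on ``REMARK 100
    TIME_NS`` lines so they survive the round trip.
    """
    if isinstance(structure, StructureModel):
        frames = [structure]
        times = list(frame_times) if frame_times is not None else [0.0]
    else:
        frames = structure.frames
        times = list(structure.frame_times)
    multi = len(frames) > 1
    with open(path, "w") as fh:
        for k, (model, t) in enumerate(zip(frames, times), start=1):
            if multi:
                fh.write(f"MODEL {k:8d}\n")
            fh.write(f"REMARK 100 TIME_NS {t:.6f}\n")
            serial = 1
            for cid, residues in model.chains.items():
                for r in residues:
                    res3 = _seq3(r.amino_acid).upper()
                    for name in ("N", "CA", "C"):
                        if r.has(name):
                            fh.write(
                                _atom_line(
                                    serial, name, res3, cid, r.position, r.atom(name)
                                )
                            )
                            serial += 1
                    for name in sorted(set(r.atoms) - {"N", "CA", "C"}):
                        fh.write(
                            _atom_line(
                                serial, name, res3, cid, r.position, r.atom(name)
                            )
                        )
                        serial += 1
                fh.write("TER\n")
            if multi:
                fh.write("ENDMDL\n")
        fh.write("END\n")


def read_pdb(path) -> TrajectoryFrames:
    """Read a (multi-model) PDB file into trajectory frames.

    A single-model file yields a one-frame trajectory. Missing time
    remarks default to the frame index in ns.
    """
    frames: list[StructureModel] = []
    times: list[float] = []
    chains: dict[str, list[Residue]] = {}
    current_time: float | None = None

    def flush_model():
        nonlocal chains, current_time
        if chains:
            frames.append(StructureModel(chains))
            times.append(
                current_time if current_time is not None else float(len(times))
            )
        chains = {}
        current_time = None

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec == "MODEL ":
                if chains:  # malformed file without ENDMDL; recover
                    flush_model()
            elif line.startswith("REMARK 100 TIME_NS"):
                current_time = float(line.split()[3])
            elif rec == "ATOM  ":
                try:
                    name = line[12:16].strip()
                    res3 = line[17:20].strip()
                    cid = line[21]
                    resseq = int(line[22:26])
                    xyz = np.array(
                        [float(line[30:38]), float(line[38:46]), float(line[46:54])]
                    )
                except ValueError as exc:
                    raise FormatError(f"{path}:{lineno}: bad ATOM record: {exc}")
                aa = _seq1(res3)
                residues = chains.setdefault(cid, [])
                if residues and residues[-1].position == resseq:
                    residues[-1].atoms[name] = xyz
                else:
                    residues.append(Residue(resseq, aa, {name: xyz}))
            elif rec == "ENDMDL":
                flush_model()
    flush_model()
    if not frames:
        raise FormatError(f"{path}: no ATOM records found")
    return TrajectoryFrames(frames, np.array(times))


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------


def write_tsv(frame: pd.DataFrame, path, float_format: str = "%.2f") -> None:
    frame.to_csv(path, sep="\t", index=False, float_format=float_format)


def format_delta_tm(frame: pd.DataFrame, decimals: int = 1) -> pd.DataFrame:
    """Render a delta-Tm report with 'ND' in place of missing values."""
    out = frame.copy()
    for col in ("tm", "dtm_vs_reference", "dtm_nonreduced_minus_reduced"):
        out[col] = [
            "ND" if pd.isna(v) else f"{v:.{decimals}f}" for v in out[col]
        ]
    return out.drop(columns=["not_determined"])


def write_tm_matrix(results: list[MeltingResult], path) -> pd.DataFrame:
    """Sample x condition matrix of Tm values, ND where undetermined."""
    samples = sorted({r.sample_id for r in results})
    conditions = ["non_reduced", "reduced"]
    data = {}
    for cond in conditions:
        col = {}
        for r in results:
            if r.condition == cond:
                col[r.sample_id] = r.tm_label()
        data[cond] = [col.get(s, "") for s in samples]
    matrix = pd.DataFrame(data, index=pd.Index(samples, name="sample_id"))
    matrix.to_csv(path, sep="\t")
    return matrix


def write_melting_results_json(results: list[MeltingResult], path) -> None:
    payload = [
        {
            "sample_id": r.sample_id,
            "condition": r.condition,
            "tm": r.tm,
            "not_determined": not r.determined,
            "derivative_peak_height": (
                None if np.isnan(r.derivative_peak_height)
                else r.derivative_peak_height
            ),
            "smoothing_window": r.smoothing_window,
            "truncated_low": r.truncated_low,
            "truncated_high": r.truncated_high,
        }
        for r in results
    ]
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_melting_results_json(path) -> list[MeltingResult]:
    payload = json.loads(Path(path).read_text())
    return [
        MeltingResult(
            sample_id=item["sample_id"],
            condition=item["condition"],
            tm=item["tm"],
            derivative_peak_height=(
                float("nan")
                if item.get("derivative_peak_height") is None
                else item["derivative_peak_height"]
            ),
            smoothing_window=item.get("smoothing_window", 0),
            truncated_low=item.get("truncated_low", False),
            truncated_high=item.get("truncated_high", False),
        )
        for item in payload
    ]


def write_distance_tsv(series_list, path) -> None:
    """Time series of per-chain end-to-end distances: time_ns chain distance_A."""
    rows = []
    for s in series_list:
        for t, d in zip(s.times, s.distances):
            rows.append({"time_ns": t, "chain": s.chain, "distance_A": d})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.3f")
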