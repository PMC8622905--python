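"""The end-to-end analysis: design -> annotate -> stability -> geometry.

:func:`run_paper_analysis` chains the stages of the study on the embedded
fixtures: designs the two wild-type fragments and their four mutants,
annotates the heptad register and places each mutation on the coiled-coil
wheel, computes theoretical monomer/dimer masses, derives the delta-Tm
report from the measured Tm table (or from fitted melting curves when CSVs
are supplied), and optionally runs the synthetic-trajectory end-to-end
distance analysis. The run is deterministic for a given config seed.
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path

import pandas as pd

from . import cdmelt, fixtures, io, seqcore, synthgen, trajgeom
from .config import RunConfig
from .errors import CcmeltError

logger = logging.getLogger("ccmelt")


def _hash(text: str) -> str:
    return hashlib.sha256(text.encode()).hexdigest()[:12]


def run_paper_analysis(
    config: RunConfig | None = None,
    melting_curves: list[cdmelt.MeltingCurve] | None = None,
) -> dict:
    """Run the full fixture-driven analysis; returns the report bundle.

    When ``melting_curves`` is given, Tm values are fitted from those
    curves instead of taken from the measured-Tm fixture. If
    ``config.output_dir`` is set, TSV/JSON reports are written there.
    """
    config = config or RunConfig()
    config.validate()

    bundle: dict = {}
    try:
        bundle["design"] = _design_stage(config)
        bundle["wheel"] = _wheel_stage(config)
        bundle["masses"] = _mass_stage(config)
        results = _melting_results(config, melting_curves)
        bundle["melting_results"] = results
        bundle["delta_tm"] = _delta_stage(results)
        if config.include_trajectory:
            bundle["distances"] = _trajectory_stage(config)
    except CcmeltError as exc:
        raise CcmeltError(f"pipeline aborted: {exc}") from exc

    bundle["notes"] = _design_notes(bundle["design"])
    if config.output_dir:
        _write_bundle(bundle, results, Path(config.output_dir))
    return bundle


def _fragments(config: RunConfig) -> dict[str, seqcore.FragmentSpec]:
    """Wild-type and mutant fragments keyed by their sample ids."""
    wt = {
        "Tpm1.1": seqcore.design_fragment(
            fixtures.tpm1_region(), 64, 154, config.fusion_tag
        ),
        "Tpm3.12": seqcore.design_fragment(
            fixtures.tpm3_region(), 65, 155, config.fusion_tag
        ),
    }
    frags = {f.fragment_id: f for f in wt.values()}
    for mutation in fixtures.MUTATIONS.values():
        base = wt[mutation.isoform_id]
        mutant = seqcore.apply_mutation(base, mutation)
        frags[f"{base.fragment_id}_{mutation.label}"] = mutant
    return frags


def _design_stage(config: RunConfig) -> pd.DataFrame:
    frags = _fragments(config)
    logger.info(
        "design: %d fragments, fixture hash %s",
        len(frags),
        _hash(fixtures.TPM1_FRAGMENT_SEQUENCE + fixtures.TPM3_FRAGMENT_SEQUENCE),
    )
    anchors = config.anchors
    rows = []
    for sample_id, frag in sorted(frags.items()):
        anchor = anchors[frag.isoform_id]
        region = fixtures.isoform_region(frag.isoform_id)
        annotation = seqcore.assign_heptad(
            region, anchor[0], anchor[1], config.period_maps.get(frag.isoform_id)
        )
        rows.append(
            {
                "sample_id": sample_id,
                "isoform": frag.isoform_id,
                "start": frag.start,
                "end": frag.end,
                "tpm_length": frag.tpm_length,
                "peptide_length": len(frag.peptide_sequence),
                "n_heptads": seqcore.count_heptads(frag, annotation),
                "peptide_sequence": frag.peptide_sequence,
            }
        )
    return pd.DataFrame(rows)


def _wheel_stage(config: RunConfig) -> pd.DataFrame:
    frames = []
    for isoform in ("Tpm1.1", "Tpm3.12"):
        region = fixtures.isoform_region(isoform)
        anchor = config.anchors[isoform]
        annotation = seqcore.assign_heptad(
            region, anchor[0], anchor[1], config.period_maps.get(isoform)
        )
        muts = [
            m for m in fixtures.MUTATIONS.values() if m.isoform_id == isoform
        ]
        frames.append(seqcore.wheel_report(annotation, muts))
    wheel = pd.concat(frames, ignore_index=True)
    logger.info("wheel: %d mutations placed", len(wheel))
    return wheel


def _mass_stage(config: RunConfig) -> pd.DataFrame:
    rows = []
    for sample_id, frag in sorted(_fragments(config).items()):
        mono = seqcore.molecular_weight(frag.peptide_sequence, "monomer")
        dimer = seqcore.molecular_weight(frag.peptide_sequence, "disulfide_dimer")
        rows.append(
            {
                "sample_id": sample_id,
                "monomer_Da": round(mono, 2),
                "disulfide_dimer_Da": round(dimer, 2),
            }
        )
    return pd.DataFrame(rows)


def _melting_results(
    config: RunConfig, curves: list[cdmelt.MeltingCurve] | None
) -> list[cdmelt.MeltingResult]:
    if curves is None:
        logger.info("melting: using measured-Tm fixture (12 entries)")
        return fixtures.table1_results()
    logger.info("melting: fitting %d curves", len(curves))
    return [
        cdmelt.melt_tm(
            c, window=config.melt_window,
            truncation_threshold=config.truncation_threshold,
        )
        for c in curves
    ]


def _delta_stage(results: list[cdmelt.MeltingResult]) -> pd.DataFrame:
    parts = []
    sample_ids = {r.sample_id for r in results}
    for isoform, wt_id in fixtures.WILD_TYPE_IDS.items():
        group = [
            r for r in results
            if r.sample_id == wt_id or r.sample_id.startswith(wt_id + "_")
        ]
        if not group or wt_id not in {r.sample_id for r in group}:
            continue
        parts.append(cdmelt.delta_tm_report(group, wt_id))
    if not parts:
        # no recognised wild types: report everything against the first id
        parts = [cdmelt.delta_tm_report(results, sorted(sample_ids)[0])]
    return pd.concat(parts, ignore_index=True)


def _trajectory_stage(config: RunConfig) -> pd.DataFrame:
    frag = fixtures.tpm1_fragment()
    cp = config.crick
    if cp.n_residues != len(frag.peptide_sequence):
        cp = synthgen.CrickParams(n_residues=len(frag.peptide_sequence))
    model = synthgen.build_coiled_coil(
        frag.peptide_sequence, cp,
        first_position=frag.tag_numbering[0] if frag.tag_numbering else frag.start,
    )
    pp = config.perturbation
    pp = synthgen.PerturbationParams(
        n_frames=pp.n_frames,
        bend_amplitude=pp.bend_amplitude,
        fray_length=pp.fray_length,
        fray_amplitude=pp.fray_amplitude,
        frame_interval_ns=pp.frame_interval_ns,
        seed=config.seed,
    )
    frames = synthgen.perturb_trajectory(model, pp)
    reference = frames.frames[-1]  # spans fixed on the final frame
    series = []
    for chain in reference.chain_ids:
        span = trajgeom.helix_span(reference, chain)
        if span is None:
            continue
        series.append(
            trajgeom.end_to_end(
                frames, chain, span.first_helical_residue, span.last_helical_residue
            )
        )
    logger.info("trajectory: %d frames, %d chains", frames.n_frames, len(series))
    return trajgeom.summarize_series(series)


def _design_notes(design: pd.DataFrame) -> list[str]:
    notes = []
    lengths = sorted(set(design["peptide_length"]))
    notes.append(
        f"designed peptide length = {lengths[0]} residues "
        f"({len(fixtures.FUSION_TAG)}-residue tag + 91-residue Tpm portion); "
        "reported lengths are computed from the sequences"
    )
    return notes


def _write_bundle(bundle: dict, results, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    io.write_tsv(bundle["design"], outdir / "design.tsv")
    io.write_tsv(bundle["wheel"], outdir / "wheel.tsv")
    io.write_tsv(bundle["masses"], outdir / "masses.tsv")
    io.write_tsv(
        io.format_delta_tm(bundle["delta_tm"]), outdir / "delta_tm.tsv"
    )
    io.write_tm_matrix(results, outdir / "tm_matrix.tsv")
    io.write_melting_results_json(results, outdir / "melting_results.json")
    if "distances" in bundle:
        io.write_tsv(bundle["distances"], outdir / "distances.tsv")
    (outdir / "notes.txt").write_text("\n".join(bundle["notes"]) + "\n")
    logger.info("reports written to %s", outdir)
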