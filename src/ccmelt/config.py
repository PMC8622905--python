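"""Run configuration: a JSON-serializable bundle of analysis parameters."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

from .cdmelt import HelicityConstants
from .errors import FormatError
from .fixtures import DEFAULT_ANCHORS, DEFAULT_PERIOD_MAPS, FUSION_TAG
from .seqcore import HEPTAD_LETTERS, PeriodMap
from .synthgen import CrickParams, PerturbationParams


@dataclass
class RunConfig:
    """Parameters of a full analysis run.

    Defaults reproduce the study conditions; every field can be overridden
    from JSON. ``anchors`` maps isoform id to (position, heptad letter),
    ``period_maps`` to actin-binding period intervals.
    """

    anchors: dict[str, tuple[int, str]] = field(
        default_factory=lambda: dict(DEFAULT_ANCHORS)
    )
    period_maps: dict[str, PeriodMap] = field(
        default_factory=lambda: dict(DEFAULT_PERIOD_MAPS)
    )
    fusion_tag: str = FUSION_TAG
    melt_window: int = 7
    truncation_threshold: float = 0.2
    helicity: HelicityConstants = field(default_factory=HelicityConstants)
    crick: CrickParams = field(default_factory=CrickParams)
    perturbation: PerturbationParams = field(default_factory=PerturbationParams)
    include_trajectory: bool = False
    output_dir: str | None = None
    seed: int = 0

    def validate(self) -> None:
        for isoform, (pos, letter) in self.anchors.items():
            if letter not in HEPTAD_LETTERS:
                raise FormatError(
                    f"anchor letter {letter!r} for {isoform} not in a-g"
                )
            if int(pos) < 1:
                raise FormatError(f"anchor position {pos} must be >= 1")
        if self.melt_window % 2 == 0 or self.melt_window < 5:
            raise FormatError("melt_window must be odd and >= 5")
        if not 0.0 < self.truncation_threshold < 1.0:
            raise FormatError("truncation_threshold must lie in (0, 1)")

    def to_json(self, path) -> None:
        payload = asdict(self)
        payload["period_maps"] = {
            iso: list(pm.intervals) for iso, pm in self.period_maps.items()
        }
        payload["crick"] = {
            k: v for k, v in asdict(self.crick).items()
        }
        Path(path).write_text(json.dumps(payload, indent=2, default=float) + "\n")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        try:
            payload = json.loads(Path(path).read_text())
        except json.JSONDecodeError as exc:
            raise FormatError(f"{path}: invalid JSON: {exc}") from exc
        kwargs = {}
        if "anchors" in payload:
            kwargs["anchors"] = {
                iso: (int(p), str(letter))
                for iso, (p, letter) in payload["anchors"].items()
            }
        if "period_maps" in payload:
            kwargs["period_maps"] = {
                iso: PeriodMap(tuple((str(a), int(b), int(c)) for a, b, c in ivs))
                for iso, ivs in payload["period_maps"].items()
            }
        for key in (
            "fusion_tag",
            "melt_window",
            "truncation_threshold",
            "include_trajectory",
            "output_dir",
            "seed",
        ):
            if key in payload:
                kwargs[key] = payload[key]
        if "helicity" in payload:
            kwargs["helicity"] = HelicityConstants(**payload["helicity"])
        if "crick" in payload:
            kwargs["crick"] = CrickParams(**payload["crick"])
        if "perturbation" in payload:
            kwargs["perturbation"] = PerturbationParams(**payload["perturbation"])
        config = cls(**kwargs)
        config.validate()
        return config
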