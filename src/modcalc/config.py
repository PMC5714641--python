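"""Machine and model configuration, JSON-serializable.

Collects everything the fluence/response pipeline needs for one machine:
leaf geometry, the extrafocal source, MLC templates, the EPID kernel, the
dosimetric leaf gap, magnification, flood-field parameters and the two
sampling regimes (fine commissioning sampling and the coarser clinical
sampling used for routine second checks).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

from .epid import EPIDKernel
from .fluence import (CLINICAL_INTERVALS, CLINICAL_SPACING_UM,
                      COMMISSIONING_INTERVALS, COMMISSIONING_SPACING_UM)
from .headscatter import DEFAULT_HORN_HEIGHT, DEFAULT_HORN_RADIUS_CM, ExtrafocalSource
from .mlc_effects import TemplateSet
from .mlc_sequence import (CLOSED_GAP_THRESHOLD_MM, DEFAULT_DLG_MM,
                           LeafGeometry)


@dataclass(frozen=True)
class ModelConfig:
    geometry: LeafGeometry = field(default_factory=LeafGeometry.millennium120)
    source: ExtrafocalSource = field(default_factory=ExtrafocalSource)
    templates: TemplateSet = field(default_factory=TemplateSet)
    epid_kernel: EPIDKernel = field(default_factory=EPIDKernel.default)
    dlg_mm: float = DEFAULT_DLG_MM
    closed_exempt: bool = True
    closed_threshold_mm: float = CLOSED_GAP_THRESHOLD_MM
    magnification: float = 1.05
    flat_hsf: bool = False
    flood_mode: str = "synthetic"
    horn_height: float = DEFAULT_HORN_HEIGHT
    horn_radius_cm: float = DEFAULT_HORN_RADIUS_CM
    margin_mm: float = 30.0
    deconv_eps_rel: float = 1e-3
    commissioning_spacing_um: float = COMMISSIONING_SPACING_UM
    commissioning_intervals: int = COMMISSIONING_INTERVALS
    clinical_spacing_um: float = CLINICAL_SPACING_UM
    clinical_intervals: int = CLINICAL_INTERVALS

    def replace_templates(self, templates: TemplateSet) -> "ModelConfig":
        return replace(self, templates=templates)

    def replace(self, **changes) -> "ModelConfig":
        return replace(self, **changes)

    # ------------------------------------------------------------------ #
    def to_dict(self) -> dict:
        return {
            "leaf_boundaries_mm": list(self.geometry.boundaries),
            "source": {
                "amplitudes": list(self.source.amplitudes),
                "sigmas_cm": list(self.source.sigmas),
                "z_filter_cm": self.source.z_filter,
                "z_jaw_x_cm": self.source.z_jaw_x,
                "z_jaw_y_cm": self.source.z_jaw_y,
                "backscatter_coeff": self.source.backscatter_coeff,
            },
            "templates": {
                "leak_profile": list(self.templates.leak_profile),
                "tng_profile": list(self.templates.tng_profile),
                "weight_A": self.templates.weight_A,
                "weight_B": self.templates.weight_B,
                "pixel_um": self.templates.pixel_um,
            },
            "epid_kernel": {
                "gaussians": [list(g) for g in self.epid_kernel.gaussians],
                "pixel_um": self.epid_kernel.pixel_um,
            },
            "dlg_mm": self.dlg_mm,
            "closed_exempt": self.closed_exempt,
            "closed_threshold_mm": self.closed_threshold_mm,
            "magnification": self.magnification,
            "flat_hsf": self.flat_hsf,
            "flood_mode": self.flood_mode,
            "horn_height": self.horn_height,
            "horn_radius_cm": self.horn_radius_cm,
            "margin_mm": self.margin_mm,
            "deconv_eps_rel": self.deconv_eps_rel,
            "commissioning_spacing_um": self.commissioning_spacing_um,
            "commissioning_intervals": self.commissioning_intervals,
            "clinical_spacing_um": self.clinical_spacing_um,
            "clinical_intervals": self.clinical_intervals,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        src = d.get("source", {})
        ts = d.get("templates", {})
        ker = d.get("epid_kernel", {})
        defaults = cls()
        return cls(
            geometry=(LeafGeometry(tuple(d["leaf_boundaries_mm"]))
                      if "leaf_boundaries_mm" in d else defaults.geometry),
            source=ExtrafocalSource(
                amplitudes=tuple(src.get("amplitudes",
                                         defaults.source.amplitudes)),
                sigmas=tuple(src.get("sigmas_cm", defaults.source.sigmas)),
                z_filter=src.get("z_filter_cm", defaults.source.z_filter),
                z_jaw_x=src.get("z_jaw_x_cm", defaults.source.z_jaw_x),
                z_jaw_y=src.get("z_jaw_y_cm", defaults.source.z_jaw_y),
                backscatter_coeff=src.get("backscatter_coeff",
                                          defaults.source.backscatter_coeff)),
            templates=TemplateSet(
                leak_profile=tuple(ts.get("leak_profile",
                                          defaults.templates.leak_profile)),
                tng_profile=tuple(ts.get("tng_profile",
                                         defaults.templates.tng_profile)),
                weight_A=ts.get("weight_A", defaults.templates.weight_A),
                weight_B=ts.get("weight_B", defaults.templates.weight_B),
                pixel_um=ts.get("pixel_um", defaults.templates.pixel_um)),
            epid_kernel=(EPIDKernel(tuple(tuple(g) for g in ker["gaussians"]),
                                    ker.get("pixel_um", 784.0))
                         if "gaussians" in ker else defaults.epid_kernel),
            **{k: d.get(k, getattr(defaults, k)) for k in (
                "dlg_mm", "closed_exempt", "closed_threshold_mm",
                "magnification", "flat_hsf", "flood_mode", "horn_height",
                "horn_radius_cm", "margin_mm", "deconv_eps_rel",
                "commissioning_spacing_um", "commissioning_intervals",
                "clinical_spacing_um", "clinical_intervals")},
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "ModelConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))
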