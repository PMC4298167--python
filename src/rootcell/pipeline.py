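"""Per-image orchestration of the full measurement pipeline.

Runs the selection steps in the supervised tool's order (root, stele,
central metaxylem, cortex), derives the area arithmetic, then counts cell
layers and cells per cell file on the polar-transformed image, producing
one MeasurementRecord per image.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .preprocess import CalibratedImage, PipelineParams, preprocess_chain
from .segmentation import (compute_areas, select_central_metaxylem, select_cortex,
                           select_root, select_stele)
from .polar import (count_cells_in_file, count_layers, place_file_radii,
                    polar_transform)


class PipelineError(RuntimeError):
    """A stage rejected the image; carries the stage name and reason."""

    def __init__(self, stage: str, reason: str):
        super().__init__(f"{stage}: {reason}")
        self.stage = stage
        self.reason = reason


@dataclasses.dataclass
class MeasurementRecord:
    """One image's full output row (the tool's tabulated parameters).

    Areas are in px (unit "px") or um^2 (unit "um2"); ``nm`` is None when
    no manual metaxylem count was supplied.
    """

    image_id: str
    unit: str
    roota: float
    ela: float
    ctxa: float
    stelea: float
    cma: float
    ncm: int
    nm: int | None
    ncl: float
    ncf: list
    warnings: list = dataclasses.field(default_factory=list)

    def to_dict(self) -> dict:
        d = {"image_id": self.image_id, "unit": self.unit,
             "ROOTA": self.roota, "ELA": self.ela, "CTXA": self.ctxa,
             "STELEA": self.stelea, "CMA": self.cma, "NCM": self.ncm,
             "NM": self.nm, "NCL": self.ncl}
        for i, v in enumerate(self.ncf, start=1):
            d[f"NCF{i}"] = v
        return d


@dataclasses.dataclass
class PipelineArtifacts:
    """Everything a run produced, for overlays and ROI export."""

    record: MeasurementRecord
    selections: dict
    layer_profiles: list
    file_profiles: list
    polar_center: tuple
    n_angles: int = 720


def _boundary_radius_per_angle(mask: np.ndarray, center, n_angles: int, r_max: int):
    from .polar import polar_transform as _pt
    pol = _pt(mask.astype(np.float64), center, n_angles, r_max)
    ext = pol.pixels >= 0.5
    out = np.zeros(n_angles)
    for a in range(n_angles):
        nz = np.nonzero(ext[:, a])[0]
        out[a] = nz.max() if nz.size else 0.0
    return out


def run_pipeline(img: CalibratedImage, params: PipelineParams,
                 return_artifacts: bool = False):
    """Measure one image; returns a MeasurementRecord.

    Deterministic for a fixed image and params (params.rng_seed seeds the
    counting-line placement).  Any stage rejection raises PipelineError.
    """
    warnings: list = []

    def _stage(name, fn, *a, **kw):
        try:
            return fn(*a, **kw)
        except ValueError as exc:
            raise PipelineError(name, str(exc)) from exc

    proc, mask, _ = _stage("preprocess", preprocess_chain, img, params)
    root = _stage("select_root", select_root, img, params, proc_mask=mask)
    stele = _stage("select_stele", select_stele, root, params.stele_proportion)
    cmx, ncm = _stage("select_central_metaxylem", select_central_metaxylem,
                      img, stele, params, proc=proc)
    cortex = _stage("select_cortex", select_cortex, img, root, stele, params, proc=proc)
    calibration = params.calibration if params.unit_mode == "calibrated" else None
    if params.unit_mode == "calibrated" and params.calibration is None:
        warnings.append("calibrated unit mode requested without a calibration; using px")
        calibration = None
    areas = _stage("compute_areas", compute_areas, root, stele, cmx, cortex, calibration)
    for sel in (root, stele, cmx, cortex):
        warnings.extend(sel.warnings)

    center = stele.centroid
    n_ang = params.n_angles
    r_max = cortex.meta.get("r_max")
    if r_max is None:
        rr, cc = np.nonzero(root.mask)
        r_max = int(np.ceil(np.hypot(rr - center[0], cc - center[1]).max())) + 5
    polar = _stage("polar_transform", polar_transform, proc, center, n_ang, r_max)

    inner_r = _boundary_radius_per_angle(stele.mask, center, n_ang, r_max)
    outer_r = cortex.meta.get("band_inner_r")
    if outer_r is None:
        outer_r = _boundary_radius_per_angle(cortex.mask, center, n_ang, r_max)
    ncl, layer_profiles = _stage("count_layers", count_layers,
                                 polar, inner_r, outer_r, params)

    radii, w = place_file_radii(layer_profiles, params.n_cell_files, params.file_radii,
                                outer_bound=float(np.mean(outer_r)))
    warnings.extend(w)
    file_profiles = []
    for r in radii:
        file_profiles.append(_stage(
            "count_cells_in_file", count_cells_in_file,
            polar, r, params.cell_file_span, params))

    unit = "um2" if calibration else "px"
    scale_attr = "area_units" if calibration else "area_px"

    def _area(x):
        return float(x)

    record = MeasurementRecord(
        image_id=img.source_id, unit=unit,
        roota=_area(areas.roota), ela=_area(areas.ela), ctxa=_area(areas.ctxa),
        stelea=_area(areas.stelea), cma=_area(areas.cma),
        ncm=int(ncm), nm=params.manual_nm, ncl=float(ncl),
        ncf=[p.extrapolated_count for p in file_profiles],
        warnings=warnings,
    )
    if not return_artifacts:
        return record
    return PipelineArtifacts(
        record=record,
        selections={"root": root, "stele": stele,
                    "central_metaxylem": cmx, "cortex": cortex},
        layer_profiles=layer_profiles, file_profiles=file_profiles,
        polar_center=center, n_angles=n_ang,
    )
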