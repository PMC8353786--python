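"""Scene and table I/O: multiband TIFF rasters plus CSV/YAML sidecars.

A scene directory holds ``dn.tif`` (12-band uint8), ``dsm.tif`` and
``dsm_soil.tif`` (float32), ``plot_rois.csv``, ``canvas_rois.csv``,
``truth.csv`` and ``meta.yaml``. ROI tables use 0-based, half-open pixel
rectangles (plot_id, row0, col0, row1, col1).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .calibration import CalibrationModel
from .synthetic import CampaignScene, PlotROI, SamplingRecord, SyntheticCampaign


def write_scene(scene: CampaignScene, directory: str | Path) -> Path:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(d / "dn.tif", scene.dn)
    tifffile.imwrite(d / "dsm.tif", scene.dsm)
    tifffile.imwrite(d / "dsm_soil.tif", scene.dsm_soil)
    _write_rois(scene.plot_rois, d / "plot_rois.csv")
    pd.DataFrame(
        [dict(canvas_id=r.plot_id, row0=r.row0, col0=r.col0, row1=r.row1,
              col1=r.col1, reflectance=refl)
         for r, refl in scene.canvas_panels]
    ).to_csv(d / "canvas_rois.csv", index=False)
    scene.truth.to_csv(d / "truth.csv", index=False)
    with open(d / "meta.yaml", "w") as fh:
        yaml.safe_dump(
            dict(dat=int(scene.dat),
                 wavelengths_nm=[int(w) for w in scene.wavelengths_nm]),
            fh,
        )
    return d


def read_scene(directory: str | Path) -> CampaignScene:
    d = Path(directory)
    with open(d / "meta.yaml") as fh:
        meta = yaml.safe_load(fh)
    rois = pd.read_csv(d / "plot_rois.csv")
    canvas = pd.read_csv(d / "canvas_rois.csv")
    return CampaignScene(
        dat=int(meta["dat"]),
        dn=tifffile.imread(d / "dn.tif"),
        dsm=tifffile.imread(d / "dsm.tif"),
        dsm_soil=tifffile.imread(d / "dsm_soil.tif"),
        canvas_panels=[
            (PlotROI(r.canvas_id, int(r.row0), int(r.col0), int(r.row1),
                     int(r.col1)), float(r.reflectance))
            for r in canvas.itertuples()
        ],
        plot_rois=_read_rois(rois),
        truth=pd.read_csv(d / "truth.csv"),
        wavelengths_nm=tuple(meta["wavelengths_nm"]),
    )


def _write_rois(rois: list[PlotROI], path: Path) -> None:
    pd.DataFrame(
        [dict(plot_id=r.plot_id, row0=r.row0, col0=r.col0,
              row1=r.row1, col1=r.col1) for r in rois]
    ).to_csv(path, index=False)


def _read_rois(table: pd.DataFrame) -> list[PlotROI]:
    return [
        PlotROI(r.plot_id, int(r.row0), int(r.col0), int(r.row1), int(r.col1))
        for r in table.itertuples()
    ]


def write_sampling(records: list[SamplingRecord], path: str | Path) -> None:
    rows = []
    for rec in records:
        row = dict(plot_id=rec.plot_id, dat=rec.dat,
                   n_bundles=rec.n_bundles, plant_density=rec.plant_density)
        for i, la in enumerate(rec.leaf_areas):
            row[f"leaf_area_{i}"] = la
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def read_sampling(path: str | Path) -> list[SamplingRecord]:
    table = pd.read_csv(path, float_precision="round_trip")
    la_cols = sorted(c for c in table.columns if c.startswith("leaf_area_"))
    return [
        SamplingRecord(
            plot_id=r.plot_id, dat=int(r.dat),
            leaf_areas=tuple(float(getattr(r, c)) for c in la_cols),
            n_bundles=int(r.n_bundles), plant_density=float(r.plant_density),
        )
        for r in table.itertuples()
    ]


def write_campaign(campaign: SyntheticCampaign, directory: str | Path) -> Path:
    """Write every scene plus the campaign-level sidecars."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    for scene in campaign.scenes:
        write_scene(scene, d / f"dat{scene.dat:03d}")
    write_sampling(campaign.sampling, d / "sampling.csv")
    pd.DataFrame([vars(c) for c in campaign.cultivars]).to_csv(
        d / "cultivars.csv", index=False
    )
    write_calibration_report(campaign.true_calibration,
                             d / "true_calibration.csv")
    with open(d / "campaign.yaml", "w") as fh:
        yaml.safe_dump(
            dict(seed=int(campaign.seed),
                 dats=[int(s.dat) for s in campaign.scenes],
                 n_cultivars=len(campaign.cultivars)),
            fh,
        )
    return d


def write_calibration_report(model: CalibrationModel, path: str | Path) -> None:
    pd.DataFrame(dict(
        wavelength_nm=model.wavelengths_nm, gain=model.gain,
        offset=model.offset, r_squared=model.r_squared,
        residual_rms=model.residual_rms,
    )).to_csv(path, index=False, float_format="%.17g")


def read_calibration(path: str | Path) -> CalibrationModel:
    t = pd.read_csv(path, float_precision="round_trip")
    kwargs = {}
    if "r_squared" in t:
        kwargs["r_squared"] = t["r_squared"].to_numpy()
    if "residual_rms" in t:
        kwargs["residual_rms"] = t["residual_rms"].to_numpy()
    return CalibrationModel(
        gain=t["gain"].to_numpy(), offset=t["offset"].to_numpy(),
        wavelengths_nm=tuple(int(w) for w in t["wavelength_nm"]), **kwargs,
    )
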