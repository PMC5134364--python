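"""Reading and writing pipeline artifacts: NIfTI grids, CSV tables, manifests."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .core import Diagnosis, GroupTemplate, SubjectRecord, TISSUES, TissueMapSet
from .normalization import FINTM
from .synthetic_cohort import Cohort, CohortParams
from .variability_stats import DifferenceResult, VariabilityResult


def _affine(spacing: tuple[float, ...]) -> np.ndarray:
    aff = np.eye(4)
    for i, s in enumerate(spacing[:3]):
        aff[i, i] = s
    return aff


def save_grid(grid: np.ndarray, spacing: tuple[float, ...], path: Path) -> Path:
    img = nib.Nifti1Image(np.asarray(grid, dtype=np.float32), _affine(spacing))
    nib.save(img, str(path))
    return path


def load_grid(path: Path) -> tuple[np.ndarray, tuple[float, ...]]:
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=float)
    zooms = img.header.get_zooms()[: data.ndim]
    return data, tuple(float(z) for z in zooms)


def save_vector_field(field: np.ndarray, spacing: tuple[float, ...],
                      path: Path) -> Path:
    """Write a channel-first vector field (deformation/velocity) as a
    multi-component NIfTI: spatial axes first, components last."""
    data = np.moveaxis(np.asarray(field, dtype=np.float32), 0, -1)
    img = nib.Nifti1Image(data, _affine(spacing))
    nib.save(img, str(path))
    return path


def load_vector_field(path: Path) -> np.ndarray:
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=float)
    return np.moveaxis(data, -1, 0)


def save_tissue_maps(maps: TissueMapSet, subject_id: str, outdir: Path) -> list[Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    return [save_grid(maps.tissue(t), maps.spacing, outdir / f"{subject_id}_{t}.nii.gz")
            for t in TISSUES]


def save_cohort(cohort: Cohort, outdir: Path) -> Path:
    """Write per-subject tissue NIfTIs plus the cohort manifest CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in cohort:
        save_tissue_maps(s.maps, s.subject_id, outdir)
        rows.append({"subject_id": s.subject_id, "age": s.age,
                     "diagnosis": s.diagnosis.value, "seed": s.seed})
    manifest = outdir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def load_cohort(outdir: Path, params: CohortParams | None = None) -> Cohort:
    outdir = Path(outdir)
    table = pd.read_csv(outdir / "manifest.csv")
    subjects = []
    for row in table.itertuples():
        grids = {}
        spacing: tuple[float, ...] = ()
        for t in TISSUES:
            grids[t], spacing = load_grid(outdir / f"{row.subject_id}_{t}.nii.gz")
        maps = TissueMapSet(gm=grids["gm"], wm=grids["wm"], csf=grids["csf"],
                            spacing=spacing)
        subjects.append(SubjectRecord(subject_id=str(row.subject_id),
                                      age=float(row.age),
                                      diagnosis=Diagnosis(row.diagnosis),
                                      seed=int(row.seed), maps=maps))
    return Cohort(subjects=subjects, params=params or CohortParams())


def fintm_filename(f: FINTM, tissue: str) -> str:
    p = f.provenance
    mod = "mod" if f.modulated else "unmod"
    return (f"{p.get('experiment_id', 'NA')}_{p.get('run_id', 0)}_"
            f"{p.get('subject_id', 'NA')}_{tissue}_{mod}_{f.fwhm_mm:g}mm.nii.gz")


def save_fintm(f: FINTM, outdir: Path) -> list[Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    return [save_grid(f.tissue(t), f.spacing, outdir / fintm_filename(f, t))
            for t in TISSUES]


def load_fintms(outdir: Path) -> list[FINTM]:
    """Reconstruct FINTMs from their provenance-encoding filenames."""
    outdir = Path(outdir)
    found: dict[tuple, dict] = {}
    for path in sorted(outdir.glob("*_gm_*mm.nii.gz")):
        stem = path.name[: -len(".nii.gz")]
        exp, run, sid, _tissue, mod, fwhm = stem.split("_")
        key = (exp, int(run), sid, mod, fwhm)
        grids = {}
        spacing: tuple[float, ...] = ()
        for t in TISSUES:
            t_path = outdir / path.name.replace("_gm_", f"_{t}_")
            grids[t], spacing = load_grid(t_path)
        found[key] = {"grids": grids, "spacing": spacing}
    out = []
    for (exp, run, sid, mod, fwhm), payload in sorted(found.items()):
        out.append(FINTM(gm=payload["grids"]["gm"], wm=payload["grids"]["wm"],
                         csf=payload["grids"]["csf"], spacing=payload["spacing"],
                         modulated=(mod == "mod"),
                         fwhm_mm=float(fwhm[: -len("mm")]),
                         provenance={"experiment_id": exp, "run_id": run,
                                     "subject_id": sid}))
    return out


def save_template(template: GroupTemplate, outdir: Path, label: str = "template") -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for t in TISSUES:
        save_grid(template.tissue(t), template.spacing,
                  outdir / f"{label}_iter{template.iteration_index}_{t}.nii.gz")
    pd.DataFrame({"iteration": np.arange(1, len(template.history) + 1),
                  "mean_abs_change": template.history}
                 ).to_csv(outdir / f"{label}_history.csv", index=False)


def save_variability(result: VariabilityResult, spacing: tuple[float, ...],
                     outdir: Path, label: str) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    save_grid(result.sd_map, spacing, outdir / f"{label}_sd.nii.gz")
    save_grid(result.mean_map, spacing, outdir / f"{label}_mean.nii.gz")
    save_grid(result.mask.astype(np.uint8), spacing, outdir / f"{label}_mask.nii.gz")
    edges, fractions = result.histogram
    pd.DataFrame({"bin_edge": edges[:-1], "fraction": fractions}
                 ).to_csv(outdir / f"{label}_hist.csv", index=False)
    pd.DataFrame(result.profile, columns=["mean", "sd"]
                 ).to_csv(outdir / f"{label}_profile.csv", index=False)


def save_difference(result: DifferenceResult, spacing: tuple[float, ...],
                    outdir: Path, label: str) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    save_grid(result.diff_map, spacing, outdir / f"{label}_diff.nii.gz")
    edges, fractions = result.histogram
    pd.DataFrame({"bin_edge": edges[:-1], "fraction": fractions}
                 ).to_csv(outdir / f"{label}_diff_hist.csv", index=False)
    with open(outdir / f"{label}_fractions.json", "w") as fh:
        json.dump(result.fractions, fh, indent=2)


def write_manifest(manifest: dict, path: Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return path
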