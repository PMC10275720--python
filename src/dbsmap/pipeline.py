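"""End-to-end seeded runs of the two analyses, with a single parameter
registry (RunConfig) whose defaults are the published parameters of this
analysis family (0.2 V/mm, 0.14 S/m, 20 % coverage, 0.5 mm FD, 6 mm FWHM,
0.01-0.08 Hz, 1000 permutations)."""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import yaml

from . import connectome as conn
from . import efield, netmap, sweetspot, synthetic
from .images import save_nifti


@dataclass
class RunConfig:
    """Every numeric default of the pipeline, defined exactly once."""

    # stimulation-volume model
    efield_threshold: float = 0.2      # V/mm
    conductivity: float = 0.14         # S/m
    mode: str = "current"
    # sweetspot
    min_coverage_fraction: float = 0.2
    # connectome QC + preprocessing
    fd_threshold: float = 0.5          # mm
    fd_fraction: float = 0.5
    fwhm: float = 6.0                  # mm
    band_low: float = 0.01             # Hz
    band_high: float = 0.08            # Hz
    global_signal: bool = True
    # validation
    n_perm: int = 1000
    seed: int = 42
    # synthetic-data scale
    grid_spacing: float = 1.0          # mm, cohort analysis grid
    n_patients: int = 20
    cohort_noise_sd: float = 15.0
    n_subjects: int = 107
    n_violators: int = 7
    n_volumes: int = 180
    tr: float = 2.0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def _write_json(path, payload) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def run_sweetspot_pipeline(config: RunConfig, out_dir,
                           cohort_table=None, volumes_dir=None) -> Path:
    """Stimulation volumes -> T-model -> permutation validation -> COG.

    Without ``cohort_table`` a synthetic cohort with a planted sweetspot is
    generated (seeded from the config). With one, electrode descriptions are
    read from the table and stimulation volumes are recomputed (or, if
    ``volumes_dir`` is given, loaded as per-patient NIfTI masks named
    ``<patient_id>.nii.gz``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.save(out / "config.yaml")
    grid = synthetic.cohort_grid(config.grid_spacing)
    atlas = synthetic.make_phantom_atlas(*grid)
    report_warnings: list[str] = []
    if cohort_table is None:
        spec = synthetic.CohortSpec(n_patients=config.n_patients,
                                    noise_sd=config.cohort_noise_sd,
                                    seed=config.seed, grid=grid)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            records = synthetic.simulate_cohort(
                spec, atlas, config.efield_threshold, config.conductivity)
            report_warnings += [str(w.message) for w in caught]
        synthetic.write_cohort_table(records, out / "cohort.tsv")
    else:
        records = synthetic.read_cohort_table(cohort_table)
    improvements = [r.improvement_pct for r in records]

    if volumes_dir is not None:
        from .images import load_nifti
        volumes = []
        for r in records:
            p = Path(volumes_dir) / f"{r.patient_id}.nii.gz"
            if not p.exists():
                raise FileNotFoundError(
                    f"stimulation volume for patient {r.patient_id} not found "
                    f"at {p}")
            mask = load_nifti(p)
            volumes.append(efield.StimulationVolume(
                mask, r.patient_id, "combined",
                empty=not np.any(mask.data)))
    else:
        volumes = synthetic.cohort_stimulation_volumes(
            records, grid, config.efield_threshold, config.conductivity)

    vta_dir = out / "stimulation_volumes"
    vta_dir.mkdir(exist_ok=True)
    for v in volumes:
        save_nifti(vta_dir / f"{v.patient_id}.nii.gz", v.mask)

    model = sweetspot.compute_tmodel(volumes, improvements,
                                     config.min_coverage_fraction)
    save_nifti(out / "t_map.nii.gz", model.t_map)
    save_nifti(out / "coverage.nii.gz", model.coverage)
    save_nifti(out / "included.nii.gz", model.included)

    result = sweetspot.validate_sweetspot(model, volumes, improvements,
                                          n_perm=config.n_perm,
                                          seed=config.seed)
    pos_t = model.t_map.data[(model.included.data > 0)
                             & (model.t_map.data > 0)
                             & np.isfinite(model.t_map.data)]
    report = result.to_dict()
    report["cog_mm"] = None
    if pos_t.size:
        # per-hemisphere COG: with bilateral stimulation the map is near
        # mirror-symmetric, so a whole-map centroid would sit on the midline
        thr = float(np.percentile(pos_t, 75))
        right = synthetic.hemisphere_mask(grid, "right")
        try:
            report["cog_mm"] = [round(float(c), 6) for c in
                                sweetspot.sweetspot_cog(model, thr, region=right)]
            report["cog_t_threshold"] = round(thr, 6)
        except ValueError as exc:
            report_warnings.append(f"COG undefined: {exc}")
    else:
        report_warnings.append("no positive-t voxel: COG undefined")
    report["n_patients"] = len(records)
    report["n_included_voxels"] = model.n_included
    report["warnings"] = report_warnings
    _write_json(out / "report.json", report)
    return out


def run_network_pipeline(config: RunConfig, out_dir) -> Path:
    """Connectome QC + assembly -> fingerprints -> R-map -> validation.

    Runs on synthetic data: connectome subjects (including deliberate QC
    violators) and a patient cohort whose improvement is generated from
    connectivity to a planted network.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.save(out / "config.yaml")
    spec = synthetic.ConnectomeSpec(n_subjects=config.n_subjects,
                                    n_violators=config.n_violators,
                                    n_volumes=config.n_volumes,
                                    tr=config.tr, seed=config.seed)

    # QC on motion traces first, so excluded subjects' BOLD is never built
    fd_summary = {}
    retained_ids = []
    for i in range(spec.n_subjects):
        sid = f"conn-{i + 1:03d}"
        fd = conn.compute_fd(synthetic.simulate_motion_trace(spec, i))
        frac = float(np.count_nonzero(fd > config.fd_threshold) / fd.size)
        keep = not frac > config.fd_fraction
        fd_summary[sid] = {"mean_fd": round(float(fd.mean()), 6),
                           "max_fd": round(float(fd.max()), 6),
                           "frac_above_threshold": round(frac, 6),
                           "retained": keep}
        if keep:
            retained_ids.append(i)
    _write_json(out / "qc_report.json", {
        "n_subjects": spec.n_subjects,
        "n_retained": len(retained_ids),
        "n_excluded": spec.n_subjects - len(retained_ids),
        "fd_threshold_mm": config.fd_threshold,
        "volume_fraction": config.fd_fraction,
        "subjects": fd_summary})
    if not retained_ids:
        raise RuntimeError("all subjects excluded by motion QC")

    matrices = []
    for i in retained_ids:
        subject = synthetic.simulate_connectome_subject(spec, i)
        matrices.append(conn.preprocess_subject(
            subject, fwhm=config.fwhm, band=(config.band_low, config.band_high),
            global_signal=config.global_signal))

    seeds, improvements = synthetic.simulate_network_cohort(
        spec, n_patients=config.n_patients, seed=config.seed)
    fp_dir = out / "fingerprints"
    fp_dir.mkdir(exist_ok=True)
    fingerprints = []
    for seed_vol in seeds:
        maps = [netmap.seed_fingerprint(seed_vol, m) for m in matrices]
        fp = netmap.group_fingerprint(maps, seed_vol.patient_id)
        fingerprints.append(fp)
        save_nifti(fp_dir / f"{seed_vol.patient_id}.nii.gz", fp.zmap)

    rmap = netmap.compute_rmap(fingerprints, improvements)
    save_nifti(out / "rmap.nii.gz", rmap.rmap)
    result = netmap.validate_network_model(fingerprints, improvements,
                                           n_perm=config.n_perm,
                                           seed=config.seed)
    report = result.to_dict()
    report["n_patients"] = len(seeds)
    report["n_connectome_subjects"] = len(retained_ids)
    _write_json(out / "report.json", report)
    return out
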