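#!/usr/bin/env python
"""Network mapping: seed each patient's stimulation volume in the assembled
connectome, average the per-subject correlation maps (Fisher-Z of the mean)
into connectivity fingerprints, correlate fingerprint values with clinical
improvement voxel-wise (R-map), and validate the model by correlating
fingerprint/R-map spatial similarity with improvement under permutation.

Reads results/connectome/ (run 03 first); the patient cohort is the planted
network-cohort generator, whose improvement follows connectivity to the
first planted network. Writes the R-map and a report under results/network/.
"""

import json
from pathlib import Path

import numpy as np

from dbsmap import synthetic as syn
from dbsmap.connectome import ConnectomeMatrix
from dbsmap.netmap import (compute_rmap, group_fingerprint, seed_fingerprint,
                           spatial_similarity, validate_network_model)
from dbsmap.images import save_nifti
from dbsmap.pipeline import RunConfig

ROOT = Path(__file__).resolve().parent.parent / "results"
N_SUBJECTS, N_VIOLATORS = 20, 2  # must match 03_build_connectome


def main() -> None:
    cfg = RunConfig()
    conn_dir = ROOT / "connectome"
    out = ROOT / "network"
    out.mkdir(parents=True, exist_ok=True)

    matrices = [ConnectomeMatrix.load(p)
                for p in sorted(conn_dir.glob("conn-*.npz"))]
    spec = syn.ConnectomeSpec(n_subjects=N_SUBJECTS, n_violators=N_VIOLATORS,
                              n_volumes=cfg.n_volumes, tr=cfg.tr,
                              seed=cfg.seed)
    seeds, improvements = syn.simulate_network_cohort(
        spec, n_patients=cfg.n_patients, seed=cfg.seed)

    fingerprints = []
    for sv in seeds:
        maps = [seed_fingerprint(sv, m) for m in matrices]
        fingerprints.append(group_fingerprint(maps, sv.patient_id))

    rmap = compute_rmap(fingerprints, improvements)
    save_nifti(out / "rmap.nii.gz", rmap.rmap)
    sims = [spatial_similarity(f, rmap) for f in fingerprints]
    result = validate_network_model(fingerprints, improvements,
                                    n_perm=cfg.n_perm, seed=cfg.seed)

    report = result.to_dict()
    report["n_connectome_subjects"] = len(matrices)
    report["n_patients"] = len(seeds)
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))

    print(f"fingerprints: {len(seeds)} patients x {len(matrices)} connectome "
          f"subjects (average r, then Fisher Z)")
    print(f"  similarity range across patients: "
          f"[{min(sims):.3f}, {max(sims):.3f}]")
    print(f"  network model validation: R = {result.observed_r:.3f}, "
          f"permuted p = {result.permuted_p:.4f} ({cfg.n_perm} permutations)")
    print(f"outputs in {out}")


if __name__ == "__main__":
    main()
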