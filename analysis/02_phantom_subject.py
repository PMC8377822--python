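#!/usr/bin/env python
"""Run one RV-like phantom subject end to end through the pipeline.

Generates a moderately regurgitant phantom (s = 0.6) with mild noise and a
background phase offset, writes it to NIfTI/YAML as a scanner export would
look, then runs the full measurement chain (read, background correction,
noise screening, plane division, time series, windows, peaks) and writes
the metrics artifacts plus a vorticity map under results/subject_demo/.
"""

import json
import tempfile
from pathlib import Path

import yaml

import rvflow.fields as fio
from rvflow.hemodynamics import curl, export_vorticity_map
from rvflow.phantom import PhantomSpec, make_rv_phantom
from rvflow.pipeline import RunConfig, run_subject

OUT = Path(__file__).resolve().parent.parent / "results" / "subject_demo"


def main() -> None:
    spec = PhantomSpec(pr_severity=0.6, noise_sd=0.01, seed=11,
                       background_offset={"constant": (0.02, -0.01, 0.015)})
    ph = make_rv_phantom(spec)
    OUT.mkdir(parents=True, exist_ok=True)
    with tempfile.TemporaryDirectory() as tmp:
        tmp = Path(tmp)
        vpaths = tuple(str(tmp / f"v{c}.nii.gz") for c in "xyz")
        fio.write_velocity_field(ph.field, vpaths)
        fio.write_labels(ph.rv_mask, tmp / "rv.nii.gz")
        fio.write_labels(ph.static_mask, tmp / "static.nii.gz")
        fio.save_landmarks(ph.landmarks, tmp / "lm.yaml")
        (tmp / "meta.yaml").write_text(yaml.safe_dump({
            "subject_id": "demo",
            "systole_phase_range": list(ph.windows.systole),
            "diastole_phase_range": list(ph.windows.diastole),
            "static_tissue_label": 1}))
        cfg = RunConfig(velocity_paths=vpaths, rv_mask_path=str(tmp / "rv.nii.gz"),
                        static_mask_path=str(tmp / "static.nii.gz"),
                        landmarks_path=str(tmp / "lm.yaml"),
                        meta_path=str(tmp / "meta.yaml"),
                        out_dir=str(OUT), venc=spec.venc, subject_id="demo")
        metrics = run_subject(cfg)

    # diastolic vorticity map for rendering
    p_dia = ph.windows.diastole[0] + 2
    vort = curl(ph.field, p_dia, ph.regions.labels > 0)
    export_vorticity_map(vort, OUT / "omega_diastole.nii.gz")

    print(json.dumps(metrics.to_dict(), indent=2, sort_keys=True))
    print(f"\nPhantom at severity s = {spec.pr_severity}: the diastolic RVOT "
          f"vorticity ({metrics.omega_rvot_diastole:.1f}/s) exceeds the "
          f"attenuated inflow vortex ({metrics.omega_inflow_diastole:.1f}/s), "
          f"giving RV-DVQ = {metrics.rv_dvq:.2f}.")


if __name__ == "__main__":
    main()
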