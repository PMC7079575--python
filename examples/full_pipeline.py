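"""Full file-based pipeline: simulate a trial bundle, then run
model -> IK -> inverse dynamics -> residual reduction -> static
optimization -> kinematic validation, exactly as the `caninegait` command
line does.
"""

import tempfile
from pathlib import Path

from caninegait.io import grf_to_mot, save_model, write_trc
from caninegait.pipeline import PipelineConfig, run_pipeline
from caninegait.synthetic import SyntheticGaitSpec, generate_morphology, generate_trial

work = Path(tempfile.mkdtemp(prefix="caninegait_"))
spec = SyntheticGaitSpec(seed=2, marker_noise_mm=2.0)
model, _ = generate_morphology(spec)
trial = generate_trial(spec, model)
save_model(work / "model.yaml", model)
write_trc(work / "markers.trc", trial.markers)
grf_to_mot(work / "grf.mot", trial.grf)
print(f"synthetic bundle written to {work}")

result = run_pipeline(PipelineConfig(
    model_path=str(work / "model.yaml"),
    markers_path=str(work / "markers.trc"),
    grf_path=str(work / "grf.mot"),
    output_dir=str(work / "results"),
    seed=2,
))
print(f"gait cycle: frames {result.cycle.start_frame}-{result.cycle.end_frame}, "
      f"stance fraction {result.cycle.stance_fraction:.2f}")
for v in result.validation:
    print(" ", v.describe())
print("outputs:", ", ".join(sorted(result.outputs)))
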