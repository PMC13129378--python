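"""Miniature end-to-end run: train both networks, propagate, evaluate.

A scaled-down version of the full comparison (fewer iterations and
subjects than the packaged benchmark) that still shows the mechanics:
temporal + multi-modal training, two-step field composition, and the gain
of deformable propagation over the rigid baseline.  Takes a few minutes on
one CPU.
"""

import numpy as np

from mr4dctreg import (PairSampler, PhantomConfig, TrainConfig,
                       evaluate_result, make_study, prepare_subject,
                       propagate_pipeline, propagate_rigid, records_to_frame,
                       train)
from mr4dctreg.propagation import fit_grid

train_studies = [make_study(PhantomConfig(seed=s)) for s in (0, 1)]
test_study = make_study(PhantomConfig(seed=9))

wgrid = fit_grid(train_studies[0].record.native_grid, (24, 24, 16))
subjects = [prepare_subject(s.record, wgrid, seed=0) for s in train_studies]

nets = {}
for kind, pairing in (("temporal", "ct50-to-phase"),
                      ("multimodal", "mr-to-ct50")):
    cfg = TrainConfig(kind, wgrid, iterations=120, base_channels=16, seed=0)
    nets[kind], log = train(kind, PairSampler(subjects, pairing, seed=0), cfg)
    vals = log[log["val_loss"].notna()]["val_loss"]
    print(f"{kind}: validation loss {vals.iloc[0]:.3f} -> best "
          f"{log.attrs['best_val_loss']:.3f} over {len(log) - 1} iterations")

rec = test_study.record
rigid = propagate_rigid(rec, seed=0)
pipe = propagate_pipeline(rec, nets["multimodal"], nets["temporal"], seed=0)

rows = []
for res in (rigid, pipe):
    rows += evaluate_result(res, rec.labels_ct, omega=res.omega,
                            subject=rec.subject_id)
df = records_to_frame(rows)
seen = df[df["organ"] == "seen"].groupby("method")["dsc"].mean()
print("\nmean supervised-organ Dice on the held-out phantom:")
print(seen.round(3).to_string())
print("\nThe pipeline tracks the respiratory motion that the phase-"
      "independent rigid baseline cannot.")
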