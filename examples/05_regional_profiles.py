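"""Regional BAG profiles: recover a built-in thalamic disease signature.

Per-region brain-age models are trained on healthy phantoms; an
AD-analogue cohort is generated with its thalamus-analogue 30 years
"older" than the rest of the brain. The cohort's corrected-BAG profile
should peak in exactly that region.
"""

import dataclasses

import numpy as np
import pandas as pd

import mechage as mg
from mechage.types import SUBCORTICAL_REGIONS

ph = mg.PhantomConfig(grid_shape=(32, 32, 32), n_subjects=60, seed=2)
atlas = mg.generate_atlas(ph)
hc_vols, hc_recs = mg.generate_cohort(ph, "HC", atlas)
ctrl_vols, ctrl_recs = mg.generate_cohort(
    dataclasses.replace(ph, n_subjects=20, seed=ph.seed + 104729), "HC", atlas)
pat_vols, pat_recs = mg.generate_cohort(
    dataclasses.replace(ph, n_subjects=20), "AD", atlas)

models = mg.train_regional_models(
    hc_vols, np.array([r.age for r in hc_recs]), atlas,
    list(SUBCORTICAL_REGIONS),
    mg.EncoderConfig(in_channels=2, embedding_dim=16),
    mg.TrainConfig(epochs=12, batch_size=16, seed=0))

rows = []
for region, rp in models.items():
    ctrl_ids = [f"c{r.subject_id}" for r in ctrl_recs]
    ctrl = mg.compute_bag(dict(zip(ctrl_ids, rp.predict(ctrl_vols, atlas))),
                          [dataclasses.replace(r, subject_id=f"c{r.subject_id}")
                           for r in ctrl_recs])
    bias = mg.fit_bias_correction(ctrl)
    pats = mg.apply_bias_correction(
        bias, mg.compute_bag(dict(zip([r.subject_id for r in pat_recs],
                                      rp.predict(pat_vols, atlas))), pat_recs))
    rows += [{"subject_id": b.subject_id, "cohort": "AD", "region": region,
              "corrected_bag": b.corrected_bag} for b in pats]

profile = mg.cohort_profile(pd.DataFrame(rows), "AD",
                            region_order=list(SUBCORTICAL_REGIONS))
for name, value in zip(profile.region_names, profile.values):
    print(f"{name:12s} {value:+7.2f} y")
# The thalamus-analogue shows a corrected BAG elevation of roughly +15 y
# (attenuated from the generated +30 y by regression-to-the-mean in the
# small regional model), while other regions sit near zero.
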