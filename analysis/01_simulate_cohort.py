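#!/usr/bin/env python
"""Simulate the study cohort: 45 smokers vs 44 non-smokers.

Generates the synthetic case-control cohort the downstream analyses run
on: 180 volumes at TR 3 s per subject on a 24^3 grid of 3 mm voxels
(a desk-scale field of view), spatially smooth AR(1) background noise,
and two planted synchrony effects mirroring the expected phenotype —
one region where local synchrony is REDUCED in the case group and one
where it is ELEVATED — plus a clinical coupling between craving scores
and synchrony in the elevated region.

Images and motion files land under scratch/cohort/ (large, regenerable);
the subject table is copied to results/.
"""

from pathlib import Path

import numpy as np

from rehopipe.synthetic import ClinicalLink, CohortConfig, EffectROI, generate_cohort

ROOT = Path(__file__).resolve().parents[1]
COHORT_DIR = ROOT / "scratch" / "cohort"
RESULTS = ROOT / "results"

# planted phenotype: case-group synchrony down in ROI A, up in ROI B
ROI_DECREASED = EffectROI(center=(7, 7, 7), radius_vox=2.5,
                          sync_weight_group1=0.20, sync_weight_group2=0.55)
ROI_INCREASED = EffectROI(center=(16, 16, 16), radius_vox=2.5,
                          sync_weight_group1=0.55, sync_weight_group2=0.20)

CONFIG = CohortConfig(
    effect_rois=(ROI_DECREASED, ROI_INCREASED),
    clinical_link=ClinicalLink(roi_index=1, variable="craving", strength=0.4),
    seed=20120822,
)


def main() -> None:
    table = generate_cohort(CONFIG, COHORT_DIR)
    RESULTS.mkdir(exist_ok=True)
    table.to_csv(RESULTS / "subjects.tsv", sep="\t", index=False, float_format="%.6g")

    cases = table[table["group"] == "group1"]
    controls = table[table["group"] == "group2"]
    print(f"cohort written to {COHORT_DIR}")
    print(f"  group1 (smokers):     n={len(cases)}, "
          f"age {cases['age'].mean():.1f}±{cases['age'].std():.1f}, "
          f"education {cases['education'].mean():.1f}±{cases['education'].std():.1f}, "
          f"{(cases['sex']=='F').sum()}F/{(cases['sex']=='M').sum()}M")
    print(f"  group2 (non-smokers): n={len(controls)}, "
          f"age {controls['age'].mean():.1f}±{controls['age'].std():.1f}, "
          f"education {controls['education'].mean():.1f}±{controls['education'].std():.1f}, "
          f"{(controls['sex']=='F').sum()}F/{(controls['sex']=='M').sum()}M")
    print(f"  craving (smokers): {cases['craving'].mean():.2f}±{cases['craving'].std():.2f}")
    print(f"  planted ROIs: synchrony {ROI_DECREASED.sync_weight_group1} vs "
          f"{ROI_DECREASED.sync_weight_group2} at {ROI_DECREASED.center} (decreased), "
          f"{ROI_INCREASED.sync_weight_group1} vs {ROI_INCREASED.sync_weight_group2} "
          f"at {ROI_INCREASED.center} (increased)")
    n_vox = int(np.prod(CONFIG.grid_shape))
    print(f"  per subject: {CONFIG.n_volumes} volumes, {n_vox} voxels "
          f"({'x'.join(map(str, CONFIG.grid_shape))} at "
          f"{CONFIG.voxel_size_mm[0]:g} mm), TR {CONFIG.tr_s:g} s")


if __name__ == "__main__":
    main()
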