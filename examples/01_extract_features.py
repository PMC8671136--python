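"""Extract Fisher-z connectivity features from ROI time-series files.

Simulates a tiny two-site cohort, writes it to disk in the ``.1D`` +
phenotype-CSV layout, then reads it back through the I/O layer and turns
each subject's time series into the standard connectivity feature vector:
Pearson correlation matrix -> Fisher z-transform -> strictly-lower-triangle
vectorization (R(R-1)/2 features for R regions).
"""

import tempfile
from pathlib import Path

from eiic.features import (
    SubjectRecord,
    extract_features,
    read_phenotype,
    read_roi_timeseries,
    screen_subjects,
)
from eiic.simulate import SimSpec, SiteSpec, simulate_dataset, write_fixture

spec = SimSpec(
    n_rois=20,
    sites=[
        SiteSpec(site_id="NYU", n_subjects=4, t_points=150),
        SiteSpec(site_id="UCLA", n_subjects=4, t_points=150),
    ],
    effect_edges=0.2,
    effect_size=0.6,
    seed=0,
)
records, _ = simulate_dataset(spec)

with tempfile.TemporaryDirectory() as tmp:
    out = Path(tmp) / "cohort"
    write_fixture(records, out)
    stubs = read_phenotype(out / "phenotype.csv")  # ABIDE coding: 1=case, 2=control
    cohort = []
    for stub in stubs:
        ts, roi_names = read_roi_timeseries(out / f"{stub.subject_id}_rois.1D")
        cohort.append(SubjectRecord(stub.subject_id, stub.site_id, stub.label, ts))

kept, log = screen_subjects(cohort)
features = extract_features(kept)

print(f"subjects read: {len(cohort)}; kept after screening: {len(kept)}")
print(f"excluded subjects: {log.excluded_subjects}")
f = features[0]
print(f"{f.subject_id} (site {f.site_id}, label {f.label}): "
      f"{f.values.size} features, first five = {f.values[:5].round(3)}")
# 20 regions give 20*19/2 = 190 features per subject; each value is the
# Fisher z (atanh) of one region-pair correlation, so |z| around 0-1 is a
# typical connectivity strength and larger magnitudes mean stronger coupling.
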