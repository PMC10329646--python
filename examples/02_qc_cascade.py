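"""Run the aptamer QC cascade on a fixture with planted violations.

One aptamer has a divergent plate scale factor, one an excessive median
cross-plate CV, one a 40% call rate and one an 80% call rate; the cascade
must remove exactly those four, each for the right reason.
"""

import numpy as np
import pandas as pd

from proteopheno.qc import RawAptamerData, run_qc

rng = np.random.default_rng(5)
n, cols = 200, [f"APT{i:02d}" for i in range(12)]
values = pd.DataFrame(
    rng.lognormal(mean=3.0 * np.log(10), sigma=0.1 * np.log(10), size=(n, 12)),
    index=[f"S{i}" for i in range(n)], columns=cols,
)
plates = pd.Series(np.where(np.arange(n) < n // 2, "P1", "P2"), index=values.index)
scale = pd.DataFrame(1.0, index=["P1", "P2"], columns=cols)
scale.loc["P2", "APT00"] = 1.7                       # scale factor diverges > 0.5
cvs = pd.DataFrame(0.05, index=["P1", "P2"], columns=cols)
cvs.loc[:, "APT01"] = [0.20, 0.18]                   # median CV > 0.15
values.iloc[: int(0.6 * n), 2] = np.nan              # 40% call rate
values.iloc[: int(0.2 * n), 3] = np.nan              # 80% call rate

proteins, report = run_qc(RawAptamerData(values, plates, scale, cvs))

print(f"aptamers in: {len(cols)}, out: {proteins.values.shape[1]}")
for apt, reason in sorted(report.all_removed_aptamers().items()):
    print(f"  removed {apt}: {reason}")
print(f"values masked by the 1.5*IQR screen: {report.n_iqr_masked}")
print("surviving aptamers are log10 + z-scored: per-column mean ~0, sd ~1")
print(f"  column means |max|: {proteins.values.mean().abs().max():.2e}")
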