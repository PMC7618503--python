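"""Anatomy of the DLNM cross-basis.

Builds the exposure spline (natural cubic, knots at regional percentiles),
the lag spline (natural cubic on log(lag+1), intercept included) and their
tensor cross-basis, and verifies one entry against the defining sum
W[t,(j,k)] = sum_l b_j(x_{t-l}) c_k(l).
"""

import numpy as np
import pandas as pd

import tempmort as tm

rng = np.random.default_rng(3)
dates = pd.date_range("2012-01-01", periods=400, freq="D")
series = tm.TemperatureSeries("m1", dates, 24 + 5 * np.sin(np.arange(400) / 58.0)
                              + rng.normal(0, 1.5, 400))

dist = tm.pool_distribution([series])
spec = tm.spec_from_percentiles(dist, (0.10, 0.75, 0.90), max_lag=21, lag_knots=3)
print(f"exposure knots (C): {np.round(spec.exposure_spec.internal_knots, 1)}")
print(f"lag knots (log(l+1) scale): {np.round(spec.lag_spec.internal_knots, 2)}")
print(f"exposure basis dim {spec.exposure_spec.dim} x lag basis dim "
      f"{spec.lag_spec.dim} = {spec.n_columns} cross-basis columns")

xb = tm.cross_basis(series, spec)
print(f"rows: {len(xb.dates)} observation days "
      f"({xb.n_dropped_burn_in} burn-in days dropped)")

# check entry (t=0 of the matrix, column (j=1,k=2)) against the raw sum
B = tm.ns_basis(series.tmean, spec.exposure_spec)
C = spec.lag_matrix()
t = spec.max_lag
direct = sum(B[t - l, 1] * C[l, 2] for l in range(spec.max_lag + 1))
K = spec.lag_spec.dim
print(f"entry check: matrix={xb.values[0, 1 * K + 2]:.6f} direct={direct:.6f}")
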