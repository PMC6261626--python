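"""Estimate functional connectivity with the four estimators and compare them.

Builds a small synthetic recording (20 regions, 2 latent communities),
unit-normalizes it, and runs the sparse+low-rank multivariate regression
(LR-MVRC) next to the elastic-net (MVRC), correlation and partial-correlation
baselines.  Printed numbers per method: the mean edge weight inside vs
between the planted communities (the estimators should separate them) and,
for the regression methods, the numerical rank of the coefficient matrix W —
the nuclear-norm penalty is what pulls LR-MVRC's W below full rank.
"""

import numpy as np

from fcnet import (
    SolverConfig,
    SyntheticSpec,
    corr_fc,
    generate_timeseries,
    lr_mvrc,
    mvrc,
    pcorr_fc,
    symmetrize_abs,
    unit_normalize,
)

membership = np.zeros((20, 2), dtype=int)
membership[:11, 0] = 1
membership[11:, 1] = 1
spec = SyntheticSpec(n_regions=20, n_times=200, n_communities=2,
                     membership=membership, noise_sd=0.3, seed=0)
ts, _ = generate_timeseries(spec)
x = unit_normalize(ts)

w_lr, report = lr_mvrc(x, SolverConfig())
w_en, _ = mvrc(x, 0.25, 0.1, SolverConfig())
print(f"LR-MVRC converged in {report.iterations} iterations "
      f"(final residual {max(report.final_residuals):.1e})")


def rank(m):
    sv = np.linalg.svd(m, compute_uv=False)
    return int(np.sum(sv > 1e-6 * sv[0]))


estimates = {
    "LR-MVRC": (symmetrize_abs(w_lr), rank(w_lr.values)),
    "MVRC": (symmetrize_abs(w_en), rank(w_en.values)),
    "CORR": (corr_fc(x), None),
    "PCORR": (pcorr_fc(x), None),
}

off_diag = ~np.eye(20, dtype=bool)
within = (membership @ membership.T > 0) & off_diag
print(f"{'method':8s} {'within':>8s} {'between':>8s} {'rank(W)':>8s}")
for name, (adj, rk) in estimates.items():
    a = adj.values
    print(f"{name:8s} {a[within].mean():8.4f} {a[~within & off_diag].mean():8.4f}"
          f" {rk if rk is not None else '-':>8}")
print("\nwithin/between = mean edge weight inside / across the planted "
      "communities.\nBoth regression methods zero the cross-community edges "
      "outright; the nuclear\npenalty additionally drops rank(W) below full.")
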