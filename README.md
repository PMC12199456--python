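# donkey — density-based clustering by adaptive kernel density estimation

`donkey` clusters small, heterogeneous numeric data sets — in particular
per-frame feature snapshots of nonadiabatic molecular-dynamics trajectory
ensembles — without any parameter tuning. It was built for the situation a
photochemist faces after a surface-hopping simulation: a few hundred
trajectories per time frame whose distribution changes shape, density and
cluster count from frame to frame, so any algorithm that needs a
per-frame bandwidth, radius or cluster count keeps demanding re-tuning.

## The method

The underlying density of the N observations Y₁…Y_N (features normalized
to [0, 1]) is estimated with a Gaussian kernel density estimate

    f̂(x) = (1/N) Σᵢ K(x − Yᵢ | Cⁱ),

where the shared pilot covariance **C** maximizes the leave-one-out
likelihood

    L = [ Πᵢ (1/(N−1)) Σ_{j≠i} K(Yᵢ − Yⱼ | C) ]^(1/N)

via the fixed-point iteration obtained from ∇_C L = 0 (leaving each point
out of its own estimate stops the bandwidth collapsing to zero). Each
kernel is then rescaled locally by the Abramson factor
λₖ = (f̂(Yₖ)/g)^(−1/2), with g the geometric mean density, so kernels
broaden in sparse regions and sharpen in dense ones; the geometric mean of
the factors is one by construction.

Every point is assigned to the density maximum reached by a safeguarded
Newton ascent of f̂ (the analytic gradient and Hessian are available in
closed form). Maxima linked by a high pass are then merged: a first-order
saddle point (exactly one positive Hessian eigenvalue) between each
adjacent pair is located by eigenvector following, peak and saddle
densities are collected in a merging matrix **M**, and pairs merge
greedily while the relative pass height

    μ_ab = M_ab / min(M_aa, M_bb)  >  β = 1/e

— the drop of a Gaussian one standard deviation from its peak. After each
merge both diagonals are raised to the larger peak and the used
off-diagonal is zeroed, which stops low-density clusters from chaining
unrelated peaks together.

Three optional parameters exist but default to "off": a global kernel
broadening α (default 1), the merge threshold β (default 1/e), and an
outlier threshold γ (default 0) flagging points with
f̂(Yᵢ)/M_cc < γ. Changing them does not require a full re-run: α restarts
at the maxima search, β at the merge loop, γ only recomputes flags.

## Worked example

```python
import numpy as np
from donkey import KDEClustering
from donkey.datasets import make_simplex
from donkey.metrics import homogeneity_completeness_v

ds = make_simplex(2, sigma=0.1, per_cluster=100, seed=42)
res = KDEClustering(ds.points).fit()
print(res.summary())
h, c, v = homogeneity_completeness_v(ds.truth_labels, res.labels)
print(f"homogeneity={h:.4f} completeness={c:.4f} v_measure={v:.4f}")
```

```
KDE Clustering Results
==========================================================
Observations:        300
Features (kept):     2
alpha / beta / gamma: 1 / 0.367879 / 0
Abramson rescaling:  on
Covariance iterations: 103 (converged: True)
Maxima before merge: 3
Clusters after merge: 3
Merges executed:     0
Outliers flagged:    0
----------------------------------------------------------
 cluster   size   peak density
       0    100         17.397
       1    100         16.726
       2    100         16.262

homogeneity=1.0000 completeness=1.0000 v_measure=1.0000
```

Three Gaussian clusters at the vertices of a unit 2-simplex are recovered
exactly: the mode search finds three maxima of 100 members each, no merge
is needed, and all three entropy-based scores against the generating
labels are 1. `res.labels` holds the per-point labels, `res.rerun(beta=0.5)`
re-merges without re-fitting, and `res.plot()` draws the labeled scatter.

The same pipeline runs from the shell:

```bash
donkey bench --dataset circles --n 500 --seed 1 -o out/
donkey cluster -i points.csv -o result.json
donkey rerun -r result.json --beta 0.5
donkey traj traj_*.xyz --atoms 0,1,2,3 --checkpoints 40,50,70
```

`donkey traj` clusters a trajectory ensemble frame by frame: it computes
wing separation ½(R₁₂+R₃₄), rhombicity R₁₃−R₂₄ and wing length ½(R₁₄+R₂₃)
of four key carbons plus their rates of change, reduces the six features
by PCA (keeping components with explained-variance ratio above 1%),
clusters every 5 fs, and groups trajectories into reaction channels —
sets that cluster identically at every checkpoint frame.

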