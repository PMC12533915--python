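"""Derive wave-specific least-squares transform matrices (QLSV/PLSV stand-ins).

Ground truth: XYZ dipole loops as Gaussian wavelets with typical spatial
orientations; leads = Dower forward matrix @ XYZ + white noise; regress XYZ on
the 8 leads using QRS-only samples (QLSV) and P-only samples (PLSV).
"""
import numpy as np

# Dower forward matrix: rows I, II, V1..V6; columns X, Y, Z
D = np.array([
    [ 0.632, -0.235,  0.059],
    [ 0.235,  1.066, -0.132],
    [-0.515,  0.157, -0.917],
    [ 0.044,  0.164, -1.387],
    [ 0.882,  0.098, -1.277],
    [ 1.213,  0.127, -0.601],
    [ 1.125,  0.127, -0.086],
    [ 0.831,  0.076,  0.230],
])

rng = np.random.default_rng(20251002)
fs = 500.0
t = np.arange(500) / fs * 1000.0

def gauss(c, w):
    return np.exp(-((t - c) ** 2) / (2 * w ** 2))

P_xyz, Q_xyz, L_all = [], [], []
for rep in range(200):
    # random per-record orientation jitter around typical axes
    jit = lambda: rng.normal(1.0, 0.15)
    p = np.outer(gauss(180 + rng.normal(0, 5), 20), 
                 [80*jit(), 120*jit(), -30*jit()])
    q = (np.outer(gauss(400 + rng.normal(0, 3), 10), [1300*jit(), 900*jit(), -500*jit()])
         + np.outer(gauss(418 + rng.normal(0, 3), 8), [-400*jit(), -300*jit(), 600*jit()]))
    tw = np.outer(gauss(650 + rng.normal(0, 8), 45), [350*jit(), 250*jit(), -100*jit()])
    xyz = p + q + tw
    leads = xyz @ D.T + rng.normal(0, 8.0, (len(t), 8))
    pmask = (t > 120) & (t < 240)
    qmask = (t > 370) & (t < 442)
    P_xyz.append((xyz[pmask], leads[pmask]))
    Q_xyz.append((xyz[qmask], leads[qmask]))

def fit(pairs):
    X = np.vstack([l for _, l in pairs])
    Y = np.vstack([x for x, _ in pairs])
    B, *_ = np.linalg.lstsq(X, Y, rcond=None)
    return B.T  # 3 x 8

qlsv = fit(Q_xyz)
plsv = fit(P_xyz)
np.set_printoptions(precision=4, suppress=True)
print("QLSV:\n", qlsv)
print("PLSV:\n", plsv)
for name, M in [("qlsv", qlsv), ("plsv", plsv)]:
    rows = "\n".join("  ".join(f"{v: .4f}" for v in row) for row in M)
    print(f"--- {name}\n{rows}")
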