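"""Independent brute-force reference implementations.

These deliberately avoid the package's code paths: explicit Python loops
for summary statistics, normal-equations solves for regression, and a
manual odd-extension forward-backward filter built from ``lfilter``.
They exist solely to cross-check the vectorized implementations.
"""

import numpy as np
from scipy import signal


def fd_loop(motion, head_radius_mm):
    """Framewise displacement via an explicit per-frame loop."""
    motion = np.asarray(motion, dtype=float)
    fd = [0.0]
    for t in range(1, motion.shape[0]):
        total = 0.0
        for j in range(3):
            total += abs(motion[t, j] - motion[t - 1, j])
        for j in range(3, 6):
            total += head_radius_mm * abs(motion[t, j] - motion[t - 1, j])
        fd.append(total)
    return np.array(fd)


def pearson_loop(x, y):
    """Pearson correlation via explicit mean/covariance loops."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sxx = syy = 0.0
    for i in range(n):
        sxy += (x[i] - mx) * (y[i] - my)
        sxx += (x[i] - mx) ** 2
        syy += (y[i] - my) ** 2
    return sxy / np.sqrt(sxx * syy)


def filtfilt_manual(b, a, x):
    """Forward-backward filtering from first principles: odd extension by
    3*max(len(a), len(b)) samples, direct-form filtering with the standard
    step-matched initial conditions, reverse, repeat, trim."""
    x = np.asarray(x, dtype=float)
    n_pad = 3 * max(len(a), len(b))
    left = 2 * x[0] - x[1:n_pad + 1][::-1]
    right = 2 * x[-1] - x[-n_pad - 1:-1][::-1]
    ext = np.concatenate([left, x, right])
    zi = signal.lfilter_zi(b, a)
    y, _ = signal.lfilter(b, a, ext, zi=zi * ext[0])
    y = y[::-1]
    y, _ = signal.lfilter(b, a, y, zi=zi * y[0])
    return y[::-1][n_pad:-n_pad]


def regress_out_normal_equations(y, design):
    """Residualize via an explicit normal-equations solve (with intercept)."""
    y = np.asarray(y, dtype=float)
    X = np.hstack([np.ones((len(y), 1)), np.asarray(design, dtype=float)])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    return y - X @ beta


def trial_fc_bruteforce(roi1, roi2, induction_window, rest_window, design,
                        tr_seconds, band):
    """The per-trial FC pipeline rebuilt from the oracle primitives."""
    r0, r1 = rest_window
    x = np.asarray(roi1, float) - np.mean(roi1[r0:r1])
    y = np.asarray(roi2, float) - np.mean(roi2[r0:r1])
    if design is not None:
        x = regress_out_normal_equations(x, design)
        y = regress_out_normal_equations(y, design)
    b, a = signal.butter(2, list(band), btype="band", fs=1.0 / tr_seconds)
    x = filtfilt_manual(b, a, x)
    y = filtfilt_manual(b, a, y)
    i0, i1 = induction_window
    return pearson_loop(x[i0:i1], y[i0:i1])


def resting_fc_bruteforce(roi1, roi2, motion, design, head_radius_mm,
                          fd_threshold_mm, tr_seconds, band):
    """The offline resting-FC pipeline rebuilt from the oracle primitives."""
    x = regress_out_normal_equations(np.asarray(roi1, float), design)
    y = regress_out_normal_equations(np.asarray(roi2, float), design)
    fd = fd_loop(motion, head_radius_mm)
    keep = [t for t in range(len(x)) if fd[t] <= fd_threshold_mm]
    x = x[keep]
    y = y[keep]
    b, a = signal.butter(2, list(band), btype="band", fs=1.0 / tr_seconds)
    x = filtfilt_manual(b, a, x)
    y = filtfilt_manual(b, a, y)
    return pearson_loop(x, y)


def glm_betas_normal_equations(data4d, design_with_const):
    """Voxel-wise OLS betas via per-voxel normal-equations solves."""
    X = np.asarray(design_with_const, dtype=float)
    nx, ny, nz, nt = data4d.shape
    betas = np.zeros((X.shape[1], nx, ny, nz))
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                yv = data4d[i, j, k, :]
                betas[:, i, j, k] = np.linalg.solve(X.T @ X, X.T @ yv)
    return betas


def sphere_members_loop(center_voxel, radius_mm, shape, voxel_size_mm):
    """Sphere membership via a triple loop over the whole grid."""
    members = []
    cx, cy, cz = center_voxel
    for i in range(shape[0]):
        for j in range(shape[1]):
            for k in range(shape[2]):
                d = voxel_size_mm * np.sqrt(
                    (i - cx) ** 2 + (j - cy) ** 2 + (k - cz) ** 2)
                if d <= radius_mm + 1e-9:
                    members.append((i, j, k))
    return sorted(members)
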