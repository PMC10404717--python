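"""Independent brute-force reference implementations used as oracles.

Everything here is written as plain loops / textbook formulas, deliberately
ignoring the vectorized paths in the package, so agreement is meaningful.
"""

import numpy as np


def pearson_loop(x, y):
    """Textbook Pearson correlation."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    mx, my = x.mean(), y.mean()
    num = ((x - mx) * (y - my)).sum()
    den = np.sqrt(((x - mx) ** 2).sum() * ((y - my) ** 2).sum())
    return num / den


def fd_power_loop(params, head_radius):
    """Framewise displacement, volume by volume."""
    n = params.shape[0]
    fd = np.zeros(n)
    for i in range(1, n):
        d = params[i] - params[i - 1]
        fd[i] = sum(abs(d[j]) for j in range(3)) + head_radius * sum(abs(d[j]) for j in range(3, 6))
    return fd


def ols_residuals_normal_equations(X, Y):
    """Residuals from solving the normal equations explicitly."""
    beta = np.linalg.solve(X.T @ X, X.T @ Y)
    return Y - X @ beta


def scrub_censor_loop(fd, threshold, n_before, n_after, n):
    """Set of censored volume indices by direct enumeration."""
    bad = set()
    for i in range(n):
        if fd[i] > threshold:
            for j in range(i - n_before, i + n_after + 1):
                if 0 <= j < n:
                    bad.add(j)
    return bad


def sphere_voxels_loop(grid, center, radius):
    """All voxel indices whose centre is within radius mm of center."""
    out = []
    for i in range(grid.shape[0]):
        for j in range(grid.shape[1]):
            for k in range(grid.shape[2]):
                mm = grid.affine[:3, :3] @ np.array([i, j, k], float) + grid.affine[:3, 3]
                if np.linalg.norm(mm - np.asarray(center, float)) <= radius + 1e-9:
                    out.append((i, j, k))
    return set(out)


def overlap_counts_loop(sets_of_voxels, shape):
    """Per-voxel subject counts from explicit membership tests."""
    counts = np.zeros(shape, int)
    for vox_list in sets_of_voxels:
        members = {tuple(v) for v in vox_list}
        for v in members:
            counts[v] += 1
    return counts


def partial_corr_twostage(x, y, C):
    """Partial correlation by two separate OLS fits then correlating the
    residuals."""
    n = len(x)
    design = np.column_stack([np.ones(n), C])
    bx = np.linalg.solve(design.T @ design, design.T @ x)
    by = np.linalg.solve(design.T @ design, design.T @ y)
    return pearson_loop(x - design @ bx, y - design @ by)


def pairwise_distances_loop(points):
    pts = np.asarray(points, float)
    out = []
    for i in range(len(pts)):
        for j in range(i + 1, len(pts)):
            out.append(np.sqrt(((pts[i] - pts[j]) ** 2).sum()))
    return np.array(out)
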