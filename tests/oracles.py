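"""Independent brute-force reference implementations used by the tests.

Everything here is written with explicit loops and elementary formulas,
deliberately sharing no code path with the package.
"""

from collections import deque
import math

import numpy as np


# ---------------------------------------------------------------- region grow


def flood_fill_mask(pixels, seed, threshold_fraction):
    """Breadth-first 4-connected flood fill from the seed."""
    h, w = pixels.shape
    r0, c0 = seed
    limit = threshold_fraction * pixels[r0, c0]
    mask = np.zeros((h, w), dtype=bool)
    queue = deque([(r0, c0)])
    mask[r0, c0] = True
    while queue:
        r, c = queue.popleft()
        for dr, dc in ((0, 1), (0, -1), (1, 0), (-1, 0)):
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w and not mask[rr, cc] and pixels[rr, cc] >= limit:
                mask[rr, cc] = True
                queue.append((rr, cc))
    return mask


# ----------------------------------------------------------------- histogram


def histogram_moments(values):
    values = [float(v) for v in values]
    n = len(values)
    mean = sum(values) / n
    var = sum((v - mean) ** 2 for v in values) / n
    if var == 0:
        return mean, 0.0, 0.0, 0.0
    m3 = sum((v - mean) ** 3 for v in values) / n
    m4 = sum((v - mean) ** 4 for v in values) / n
    return mean, var, m3 / var**1.5, m4 / var**2


# ---------------------------------------------------------------------- glcm

OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


def glcm_matrix_bruteforce(levels, mask, direction, n_levels):
    """Symmetric normalized co-occurrence matrix by looping all pixels."""
    dr, dc = OFFSETS[direction]
    h, w = levels.shape
    mat = np.zeros((n_levels, n_levels))
    for r in range(h):
        for c in range(w):
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w and mask[r, c] and mask[rr, cc]:
                a, b = levels[r, c] - 1, levels[rr, cc] - 1
                mat[a, b] += 1
                mat[b, a] += 1
    total = mat.sum()
    return mat / total if total > 0 else None


def glcm_stats_bruteforce(p, g):
    """The 22 co-occurrence statistics by explicit summation."""
    def log2(x):
        return math.log2(x) if x > 0 else 0.0

    px = [sum(p[i][j] for j in range(g)) for i in range(g)]
    py = [sum(p[i][j] for i in range(g)) for j in range(g)]
    mu_x = sum((i + 1) * px[i] for i in range(g))
    mu_y = sum((j + 1) * py[j] for j in range(g))
    sd_x = math.sqrt(sum((i + 1 - mu_x) ** 2 * px[i] for i in range(g)))
    sd_y = math.sqrt(sum((j + 1 - mu_y) ** 2 * py[j] for j in range(g)))

    asm = contrast = corr_num = sosv = idm = entropy = 0.0
    autoc = cshade = cprom = dissi = homog = invdiff = inn = idmn = 0.0
    maxpr = 0.0
    p_sum = [0.0] * (2 * g + 1)
    p_diff = [0.0] * g
    for i in range(g):
        for j in range(g):
            v = p[i][j]
            ii, jj = i + 1, j + 1
            asm += v * v
            contrast += (ii - jj) ** 2 * v
            corr_num += ii * jj * v
            sosv += (ii - mu_x) ** 2 * v
            idm += v / (1 + (ii - jj) ** 2)
            entropy -= v * log2(v)
            autoc += ii * jj * v
            cshade += (ii + jj - mu_x - mu_y) ** 3 * v
            cprom += (ii + jj - mu_x - mu_y) ** 4 * v
            dissi += abs(ii - jj) * v
            homog += v / (1 + abs(ii - jj))
            invdiff += v / (1 + abs(ii - jj))
            inn += v / (1 + abs(ii - jj) / g)
            idmn += v / (1 + (ii - jj) ** 2 / g**2)
            maxpr = max(maxpr, v)
            p_sum[ii + jj] += v
            p_diff[abs(ii - jj)] += v
    correlation = (corr_num - mu_x * mu_y) / (sd_x * sd_y) if sd_x > 0 and sd_y > 0 else 0.0
    sum_avg = sum(k * p_sum[k] for k in range(2 * g + 1))
    sum_var = sum((k - sum_avg) ** 2 * p_sum[k] for k in range(2 * g + 1))
    sum_ent = -sum(p_sum[k] * log2(p_sum[k]) for k in range(2 * g + 1))
    diff_avg = sum(k * p_diff[k] for k in range(g))
    diff_var = sum((k - diff_avg) ** 2 * p_diff[k] for k in range(g))
    diff_ent = -sum(p_diff[k] * log2(p_diff[k]) for k in range(g))
    hx = -sum(v * log2(v) for v in px)
    hy = -sum(v * log2(v) for v in py)
    hxy1 = hxy2 = 0.0
    for i in range(g):
        for j in range(g):
            prod = px[i] * py[j]
            hxy1 -= p[i][j] * log2(prod)
            hxy2 -= prod * log2(prod)
    denom = max(hx, hy)
    imc1 = (entropy - hxy1) / denom if denom > 0 else 0.0
    imc2 = math.sqrt(max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - entropy))))
    return np.array([
        asm, contrast, correlation, sosv, idm, sum_avg, sum_var, sum_ent,
        entropy, diff_var, diff_ent, imc1, imc2,
        autoc, cshade, cprom, dissi, homog, maxpr, invdiff, inn, idmn,
    ])


def glcm_features_bruteforce(levels, mask, n_levels, directions=(0, 45, 90, 135)):
    mats = [glcm_matrix_bruteforce(levels, mask, d, n_levels) for d in directions]
    mats = [m for m in mats if m is not None]
    avg = sum(mats) / len(mats)
    return glcm_stats_bruteforce(avg.tolist(), n_levels)


# ---------------------------------------------------------------------- glrl


def _lines(levels, mask, direction):
    h, w = levels.shape
    if direction == 0:
        for r in range(h):
            yield [(levels[r, c], mask[r, c]) for c in range(w)]
    elif direction == 90:
        for c in range(w):
            yield [(levels[r, c], mask[r, c]) for r in range(h)]
    elif direction == 135:
        for off in range(-h + 1, w):
            yield [
                (levels[r, r + off], mask[r, r + off])
                for r in range(h)
                if 0 <= r + off < w
            ]
    elif direction == 45:
        for off in range(-h + 1, w):
            yield [
                (levels[h - 1 - r, r + off], mask[h - 1 - r, r + off])
                for r in range(h)
                if 0 <= r + off < w
            ]


def glrl_matrix_bruteforce(levels, mask, direction, n_levels, max_len):
    mat = np.zeros((n_levels, max_len))
    for line in _lines(levels, mask, direction):
        runs = []
        for lev, ok in line:
            lev = int(lev) if ok else 0
            if runs and runs[-1][0] == lev:
                runs[-1][1] += 1
            else:
                runs.append([lev, 1])
        for lev, length in runs:
            if lev > 0:
                mat[lev - 1, length - 1] += 1
    return mat


def glrl_features_bruteforce(levels, mask, n_levels, directions=(0, 45, 90, 135)):
    max_len = max(levels.shape)
    mats = [glrl_matrix_bruteforce(levels, mask, d, n_levels, max_len) for d in directions]
    mats = [m for m in mats if m.sum() > 0]
    r = sum(mats) / len(mats)
    g_dim, l_dim = r.shape
    nr = r.sum()
    np_pixels = int(np.asarray(mask).sum())
    sre = lre = lgre = hgre = srlge = srhge = lrlge = lrhge = 0.0
    for gi in range(g_dim):
        for li in range(l_dim):
            v = r[gi, li]
            gg, ll = gi + 1, li + 1
            sre += v / ll**2
            lre += v * ll**2
            lgre += v / gg**2
            hgre += v * gg**2
            srlge += v / (gg**2 * ll**2)
            srhge += v * gg**2 / ll**2
            lrlge += v * ll**2 / gg**2
            lrhge += v * gg**2 * ll**2
    gln = sum(r[gi, :].sum() ** 2 for gi in range(g_dim))
    rln = sum(r[:, li].sum() ** 2 for li in range(l_dim))
    return np.array([
        sre / nr, lre / nr, gln / nr, rln / nr, nr / np_pixels,
        lgre / nr, hgre / nr, srlge / nr, srhge / nr, lrlge / nr, lrhge / nr,
    ])


# ------------------------------------------------------------------- wavelet


def _symmetric_extend(x, pad_left, pad_right):
    x = list(x)
    left = list(reversed(x[:pad_left]))
    right = list(reversed(x[-pad_right:]))
    return left + x + right


def dwt1d_bruteforce(x, filt):
    """Same declared convention as the package, with explicit loops."""
    n = len(x)
    L = len(filt)
    ext = _symmetric_extend(list(x), L // 2, L)
    out = []
    for k in range((n + 1) // 2):
        out.append(sum(filt[m] * ext[2 * k + m] for m in range(L)))
    return out


def dwt2_bruteforce(image, lo, hi):
    img = np.asarray(image, dtype=float)
    a0_lo = np.array([dwt1d_bruteforce(img[:, c], lo) for c in range(img.shape[1])]).T
    a0_hi = np.array([dwt1d_bruteforce(img[:, c], hi) for c in range(img.shape[1])]).T
    def along1(mat, f):
        return np.array([dwt1d_bruteforce(mat[r, :], f) for r in range(mat.shape[0])])
    return {
        "LL": along1(a0_lo, lo), "LH": along1(a0_lo, hi),
        "HL": along1(a0_hi, lo), "HH": along1(a0_hi, hi),
    }


def subband_stats_bruteforce(coeffs):
    flat = [float(v) for v in np.asarray(coeffs).ravel()]
    n = len(flat)
    mean_abs = sum(abs(v) for v in flat) / n
    mean = sum(flat) / n
    std = math.sqrt(sum((v - mean) ** 2 for v in flat) / n)
    energy = sum(v * v for v in flat)
    entropy = 0.0
    if energy > 0:
        for v in flat:
            q = v * v / energy
            if q > 0:
                entropy -= q * math.log2(q)
    return [mean_abs, std, energy, entropy]


# ----------------------------------------------------------------------- lbp

LBP_OFFSETS = ((0, 1), (-1, 1), (-1, 0), (-1, -1), (0, -1), (1, -1), (1, 0), (1, 1))


def lbp_histogram_bruteforce(image):
    img = np.asarray(image, dtype=float)
    h, w = img.shape
    uniform_codes = []
    for code in range(256):
        bits = [(code >> k) & 1 for k in range(8)]
        if sum(bits[k] != bits[(k + 1) % 8] for k in range(8)) <= 2:
            uniform_codes.append(code)
    counts = {c: 0 for c in uniform_codes}
    n_uniform = 0
    for r in range(1, h - 1):
        for c in range(1, w - 1):
            code = 0
            for bit, (dr, dc) in enumerate(LBP_OFFSETS):
                if img[r + dr, c + dc] >= img[r, c]:
                    code |= 1 << bit
            if code in counts:
                counts[code] += 1
                n_uniform += 1
    hist = np.array([counts[c] for c in uniform_codes], dtype=float)
    return hist / n_uniform if n_uniform else hist


# --------------------------------------------------------------------- gabor


def gabor_magnitude_bruteforce(image, kernel_real, kernel_imag):
    """Reflect-padded convolution by direct window products (odd kernels)."""
    img = np.asarray(image, dtype=float)
    s = kernel_real.shape[0]
    c = s // 2
    padded = np.pad(img, c, mode="symmetric")
    kr = kernel_real[::-1, ::-1]
    ki = kernel_imag[::-1, ::-1]
    out = np.zeros_like(img)
    for i in range(img.shape[0]):
        for j in range(img.shape[1]):
            win = padded[i : i + s, j : j + s]
            out[i, j] = math.hypot(float((win * kr).sum()), float((win * ki).sum()))
    return out


# ------------------------------------------------------------------ friedman


def friedman_bruteforce(rank_table):
    """Two-step Friedman chi-square + Iman–Davenport F with explicit loops."""
    r = np.asarray(rank_table, dtype=float)
    n, k = r.shape
    mean_ranks = [sum(r[i, j] for i in range(n)) / n for j in range(k)]
    chi2 = 12.0 * n / (k * (k + 1)) * (
        sum(m * m for m in mean_ranks) - k * (k + 1) ** 2 / 4.0
    )
    denom = n * (k - 1) - chi2
    t1 = (n - 1) * chi2 / denom if abs(denom) > 1e-12 else float("inf")
    return chi2, t1


def rank_average_ties_bruteforce(scores):
    """Best score -> rank 1; ties share the average of the spanned ranks."""
    scores = list(scores)
    order = sorted(range(len(scores)), key=lambda i: -scores[i])
    ranks = [0.0] * len(scores)
    pos = 0
    while pos < len(order):
        end = pos
        while end + 1 < len(order) and scores[order[end + 1]] == scores[order[pos]]:
            end += 1
        avg = (pos + 1 + end + 1) / 2.0
        for t in range(pos, end + 1):
            ranks[order[t]] = avg
        pos = end + 1
    return ranks
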