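"""Independent reference implementations used only by the test suite.

These deliberately avoid the package's own algorithms: alignment scores
come from enumerating every alignment path; site scanning from a naive
string comparison; the studentized-range tail probability from direct
numerical quadrature of its defining double integral.
"""

import math

from scipy.stats import norm


def align_score_oracle(a: str, b: str, scheme) -> float:
    """Best global alignment score by exhaustive enumeration of all
    alignments (diagonal/up/left move sequences); a gap run of length L
    costs open + (L−1)·extend, end gaps included."""
    go, ge = scheme.gap_open, scheme.gap_extend
    best = [-math.inf]

    def column_score(cols):
        s = 0.0
        run_a = run_b = 0
        for x, y in cols:
            if x == "-":
                run_a += 1
                run_b = 0
                s -= go if run_a == 1 else ge
            elif y == "-":
                run_b += 1
                run_a = 0
                s -= go if run_b == 1 else ge
            else:
                run_a = run_b = 0
                s += scheme.score(x, y)
        return s

    def rec(i, j, cols):
        if i == len(a) and j == len(b):
            v = column_score(cols)
            if v > best[0]:
                best[0] = v
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, cols + [(a[i], b[j])])
        if i < len(a):
            rec(i + 1, j, cols + [(a[i], "-")])
        if j < len(b):
            rec(i, j + 1, cols + [("-", b[j])])

    rec(0, 0, [])
    return best[0]


_RC = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def _rc(seq: str) -> str:
    return "".join(_RC[c] for c in reversed(seq))


def scan_oracle(seq: str, probe_seq: str, max_mismatches: int, min_perfect_run: int):
    """All ungapped probe windows by naive string comparison.

    Returns {orientation: [(start, mismatches, longest_run), ...]} after
    merging overlapping windows (fewest mismatches, leftmost on ties).
    """
    k = len(probe_seq)
    out = {}
    for target, orientation in (
        (_rc(probe_seq), "antisense_compatible"),
        (probe_seq, "sense_incompatible"),
    ):
        raw = []
        for i in range(len(seq) - k + 1):
            window = seq[i : i + k]
            eq = [x == y and x != "N" for x, y in zip(window, target)]
            mm = k - sum(eq)
            if mm > max_mismatches:
                continue
            run = best = 0
            for e in eq:
                run = run + 1 if e else 0
                best = max(best, run)
            if best >= min_perfect_run:
                raw.append((i, mm, best))
        merged = []
        cluster = []
        for h in raw:
            if cluster and h[0] < cluster[-1][0] + k:
                cluster.append(h)
            else:
                if cluster:
                    merged.append(min(cluster, key=lambda x: (x[1], x[0])))
                cluster = [h]
        if cluster:
            merged.append(min(cluster, key=lambda x: (x[1], x[0])))
        out[orientation] = merged
    return out


def studentized_range_sf_oracle(q: float, k: int, df: int) -> float:
    """P(Q > q) for the studentized range, by direct double quadrature.

    CDF(q) = ∫₀^∞ f_s(s) · k ∫ φ(z) [Φ(z) − Φ(z − q·s)]^{k−1} dz ds,
    with s distributed as sqrt(χ²_df / df). Both integrals use high-order
    Gauss–Legendre rules (smooth, rapidly decaying integrands), giving
    ~1e-12 accuracy.
    """
    if q <= 0:
        return 1.0
    import numpy as np

    zn, zw = np.polynomial.legendre.leggauss(400)
    z = -9.0 + (zn + 1.0) * 9.0  # map to [-9, 9]
    zw = zw * 9.0
    sn, sw = np.polynomial.legendre.leggauss(400)
    s_hi = 1.0 + 12.0 / math.sqrt(df)  # s density is tight around 1
    s = (sn + 1.0) * s_hi / 2.0
    sw = sw * s_hi / 2.0

    ln_coef = math.log(2.0) + (df / 2.0) * math.log(df / 2.0) - math.lgamma(df / 2.0)
    with np.errstate(divide="ignore"):
        f_s = np.exp(ln_coef + (df - 1) * np.log(s) - df * s * s / 2.0)

    phi_z = norm.pdf(z)
    cdf_z = norm.cdf(z)
    # inner[i] = k ∫ φ(z) [Φ(z) − Φ(z − q·s_i)]^{k−1} dz
    shifted = norm.cdf(z[None, :] - q * s[:, None])
    inner = k * ((cdf_z[None, :] - shifted) ** (k - 1) * phi_z[None, :]) @ zw
    cdf = float((f_s * inner) @ sw)
    return min(max(1.0 - cdf, 0.0), 1.0)
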