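"""Independent reference implementations used only by the tests.

Kept deliberately naive (full-matrix dynamic programming, direct
convolution sums) so they share no code path with the package.
"""

import math


def dtw_oracle(a, b, window_fraction=0.0):
    """Full-matrix DTW with absolute local cost and the widened band
    max(ceil(w * max(n, m)), |n - m|); pure Python."""
    n, m = len(a), len(b)
    band = None
    if window_fraction > 0:
        band = max(math.ceil(window_fraction * max(n, m)), abs(n - m))
    inf = float("inf")
    acc = [[inf] * (m + 1) for _ in range(n + 1)]
    acc[0][0] = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            if band is not None and abs(i - j) > band:
                continue
            cost = abs(a[i - 1] - b[j - 1])
            acc[i][j] = cost + min(acc[i - 1][j - 1], acc[i - 1][j], acc[i][j - 1])
    return acc[n][m]


def gaussian_smooth_oracle(values, sigma):
    """Direct-sum convolution with a unit-sum Gaussian kernel of radius
    ceil(3*sigma) and mirror-about-edge boundary handling."""
    radius = math.ceil(3.0 * sigma)
    kernel = [math.exp(-(x * x) / (2.0 * sigma * sigma))
              for x in range(-radius, radius + 1)]
    total = sum(kernel)
    kernel = [k / total for k in kernel]
    n = len(values)

    def sample(i):
        # mirror about the edge sample (no repeat of the edge)
        while not 0 <= i < n:
            i = -i if i < 0 else 2 * (n - 1) - i
        return values[i]

    return [
        sum(kernel[r + radius] * sample(i + r) for r in range(-radius, radius + 1))
        for i in range(n)
    ]


def circular_convolution(x, h):
    """O(n^2) circular convolution; convolution-theorem cross-check."""
    n = len(x)
    return [sum(x[j] * h[(i - j) % n] for j in range(n)) for i in range(n)]
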