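"""Independent brute-force oracles: pure-Python scalar loops, no vectorized
shortcuts, kept deliberately separate from the implementation they check."""

import math


def _row_softmax(rows):
    out = []
    for row in rows:
        m = max(row)
        exps = [math.exp(v - m) for v in row]
        s = sum(exps)
        out.append([e / s for e in exps])
    return out


def _row_log_softmax(rows):
    out = []
    for row in rows:
        m = max(row)
        lse = m + math.log(sum(math.exp(v - m) for v in row))
        out.append([v - lse for v in row])
    return out


def _matmul_t(a, b):
    """a @ b.T for lists of rows."""
    return [[sum(x * y for x, y in zip(ra, rb)) for rb in b] for ra in a]


def _transpose(m):
    return [list(col) for col in zip(*m)]


def loop_image_centric_loss(h_p, h_s, tau):
    h_p = [list(map(float, r)) for r in h_p]
    h_s = [list(map(float, r)) for r in h_s]
    logits = [[v / tau for v in row] for row in _matmul_t(h_s, h_p)]
    targets = _row_softmax([[v / tau for v in row] for row in _matmul_t(h_p, h_p)])
    L = _transpose(logits)
    Tm = _transpose(targets)
    lsm = _row_log_softmax(L)
    ces = [sum(-t * l for t, l in zip(trow, lrow)) for trow, lrow in zip(Tm, lsm)]
    return sum(ces) / len(ces)


def loop_symmetric_clip_loss(h_p, h_s, tau):
    h_p = [list(map(float, r)) for r in h_p]
    h_s = [list(map(float, r)) for r in h_s]
    logits = [[v / tau for v in row] for row in _matmul_t(h_s, h_p)]
    sim_p = _matmul_t(h_p, h_p)
    sim_s = _matmul_t(h_s, h_s)
    avg = [[(a + b) / (2.0 * tau) for a, b in zip(ra, rb)] for ra, rb in zip(sim_p, sim_s)]
    targets = _row_softmax(avg)
    lsm1 = _row_log_softmax(logits)
    lsm2 = _row_log_softmax(_transpose(logits))
    spots = [sum(-t * l for t, l in zip(tr, lr)) for tr, lr in zip(targets, lsm1)]
    images = [sum(-t * l for t, l in zip(tr, lr)) for tr, lr in zip(targets, lsm2)]
    per = [(s + i) / 2.0 for s, i in zip(spots, images)]
    return sum(per) / len(per)


def loop_hit_at_t(truth, pred, T):
    """Set-intersection evaluation of the top-gene hit rate."""
    hits = 0
    for truth_row, pred_row in zip(truth, pred):
        pred_top = max(range(len(pred_row)), key=lambda j: (pred_row[j], -j))
        ranked = sorted(range(len(truth_row)), key=lambda j: (-truth_row[j], j))
        if {pred_top} & set(ranked[:T]):
            hits += 1
    return hits / len(truth)


def loop_topk(scores_row, k):
    """Full stable sort of one query's scores; ties to lower index."""
    order = sorted(range(len(scores_row)), key=lambda j: (-scores_row[j], j))
    return order[:k]


def loop_projection_head(z, W1, b1, W2, b2, gamma, beta, eps):
    """Scalar-loop evaluation of the projection head in evaluation mode."""
    d_in, d_o = len(W1), len(b1)
    out_rows = []
    for row in z:
        h1 = []
        for j in range(d_o):
            a = b1[j] + sum(row[i] * W1[i][j] for i in range(d_in))
            h1.append(a * 0.5 * (1.0 + math.erf(a / math.sqrt(2.0))))
        h2 = [b2[j] + sum(h1[i] * W2[i][j] for i in range(d_o)) for j in range(d_o)]
        resid = [x + y for x, y in zip(h1, h2)]
        mu = sum(resid) / d_o
        var = sum((v - mu) ** 2 for v in resid) / d_o
        inv = 1.0 / math.sqrt(var + eps)
        out_rows.append([(v - mu) * inv * g + b for v, g, b in zip(resid, gamma, beta)])
    return out_rows


def loop_extract_patch(image, x, y, patch_size):
    """Per-pixel copy with explicit bounds checks and zero padding."""
    h, w = len(image), len(image[0])
    half = patch_size // 2
    patch = [[[0, 0, 0] for _ in range(patch_size)] for _ in range(patch_size)]
    for r in range(patch_size):
        for c in range(patch_size):
            src_r = y - half + r
            src_c = x - half + c
            if 0 <= src_r < h and 0 <= src_c < w:
                patch[r][c] = list(image[src_r][src_c])
    return patch
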