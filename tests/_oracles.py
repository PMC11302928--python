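"""Straight-line, loop-based reference implementations.

These are deliberately naive (explicit spatial/kernel loops, vectorized only
over channels) and independent of the package's vectorized code paths; the
tests assert the package matches them.
"""

import math

import numpy as np


def sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


def gap_oracle(x):
    """Global average pooling by explicit double loop."""
    h, w, c = x.shape
    acc = np.zeros(c, dtype=np.float64)
    for i in range(h):
        for j in range(w):
            acc += x[i, j]
    return acc / (h * w)


def conv2d_oracle(x, weight, bias=None):
    """Same-padding stride-1 cross-correlation by explicit loops."""
    h, w, c_in = x.shape
    k = weight.shape[0]
    pad = k // 2
    c_out = weight.shape[3]
    xp = np.pad(x.astype(np.float64), ((pad, pad), (pad, pad), (0, 0)))
    out = np.zeros((h, w, c_out))
    for i in range(h):
        for j in range(w):
            for a in range(k):
                for b in range(k):
                    out[i, j] += xp[i + a, j + b] @ weight[a, b]
    if bias is not None:
        out += bias
    return out


def se_oracle(x, w1, b1, w2, b2):
    z = gap_oracle(x)
    hidden = z @ w1
    if b1 is not None:
        hidden = hidden + b1
    hidden = np.maximum(hidden, 0.0)
    e = hidden @ w2
    if b2 is not None:
        e = e + b2
    gate = sigmoid(e)
    out = np.empty_like(x, dtype=np.float64)
    for i in range(x.shape[0]):
        for j in range(x.shape[1]):
            out[i, j] = x[i, j] * gate
    return out, gate


def sa_oracle(x, weight, bias=None):
    h, w, c = x.shape
    attn = np.zeros((h, w, weight.shape[3]))
    for i in range(h):
        for j in range(w):
            logits = x[i, j] @ weight[0, 0]
            if bias is not None:
                logits = logits + bias
            attn[i, j] = sigmoid(logits)
    return x * attn, attn


def max_pool_oracle(x, p, ceil_mode=False):
    h, w, c = x.shape
    if ceil_mode:
        ho, wo = math.ceil(h / p), math.ceil(w / p)
    else:
        ho, wo = h // p, w // p
    out = np.full((ho, wo, c), -np.inf)
    for i in range(ho):
        for j in range(wo):
            for a in range(p):
                for b in range(p):
                    ii, jj = p * i + a, p * j + b
                    if ii < h and jj < w:
                        out[i, j] = np.maximum(out[i, j], x[ii, jj])
    return out


def upsample_oracle(z, out_h, out_w, p):
    c = z.shape[2]
    out = np.zeros((out_h, out_w, c))
    for i in range(out_h):
        for j in range(out_w):
            out[i, j] = z[min(i // p, z.shape[0] - 1),
                          min(j // p, z.shape[1] - 1)]
    return out


def spp_oracle(x, pool_sizes, conv_weights, conv_biases=None,
               include_input=True):
    h, w, _ = x.shape
    maps = [x.astype(np.float64)] if include_input else []
    biases = conv_biases or [None] * len(pool_sizes)
    for p, wmat, b in zip(pool_sizes, conv_weights, biases):
        pooled = max_pool_oracle(x, p, ceil_mode=True)
        reduced = np.zeros((*pooled.shape[:2], wmat.shape[1]))
        for i in range(pooled.shape[0]):
            for j in range(pooled.shape[1]):
                reduced[i, j] = pooled[i, j] @ wmat
                if b is not None:
                    reduced[i, j] += b
        maps.append(upsample_oracle(reduced, h, w, p))
    return np.concatenate(maps, axis=-1)


def fusion_oracle(inputs, weight, bias=None, activation="relu"):
    fused = np.concatenate([np.asarray(im, dtype=np.float64) for im in inputs],
                           axis=-1)
    out = conv2d_oracle(fused, weight, bias)
    if activation == "relu":
        out = np.maximum(out, 0.0)
    return out


def conv_block_oracle(x, w1, b1, w2, b2):
    y = np.maximum(conv2d_oracle(x, w1, b1), 0.0)
    return np.maximum(conv2d_oracle(y, w2, b2), 0.0)


def confusion_oracle(truth, pred, k):
    """Per-pixel counting loop."""
    tp = fp = fn = tn = 0
    for t, p in zip(truth.ravel(), pred.ravel()):
        if p == k and t == k:
            tp += 1
        elif p == k:
            fp += 1
        elif t == k:
            fn += 1
        else:
            tn += 1
    return tp, fp, fn, tn


def tversky_oracle(y_true, y_pred, alpha, beta, smooth):
    tp = fp = fn = 0.0
    for t, p in zip(np.asarray(y_true, dtype=np.float64).ravel(),
                    np.asarray(y_pred, dtype=np.float64).ravel()):
        tp += t * p
        fp += (1 - t) * p
        fn += t * (1 - p)
    return 1.0 - (tp + smooth) / (tp + alpha * fn + beta * fp + smooth)


SOBEL_GX = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=np.float64)
SOBEL_GY = SOBEL_GX.T


def sobel_oracle(img):
    """Hand convolution of the two Sobel kernels with edge replication."""
    h, w = img.shape
    xp = np.pad(img.astype(np.float64), 1, mode="edge")
    out = np.zeros((h, w))
    for i in range(h):
        for j in range(w):
            gx = gy = 0.0
            for a in range(3):
                for b in range(3):
                    gx += SOBEL_GX[a, b] * xp[i + a, j + b]
                    gy += SOBEL_GY[a, b] * xp[i + a, j + b]
            out[i, j] = math.sqrt(gx * gx + gy * gy)
    return out


def boundary_oracle(y_true, y_pred, weight=1.0):
    diffs = []
    for k in range(y_true.shape[-1]):
        diffs.append(np.abs(sobel_oracle(y_true[..., k])
                            - sobel_oracle(y_pred[..., k])))
    return weight * float(np.mean(diffs))
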