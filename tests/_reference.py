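"""Straight-line NumPy re-computations used as independent oracles.

Everything here is deliberately naive — explicit loops, no im2col, no
autodiff — so agreement with the package's vectorised/taped implementations
is meaningful.  Weights are read off the modules under test and replayed
through plain arithmetic.
"""

from __future__ import annotations

import numpy as np


def conv2d_ref(x, w, b=None, stride=1, padding=0, dilation=1, groups=1):
    """Naive NCHW cross-correlation with explicit loops."""
    B, C, H, W = x.shape
    Cout, Cg, kh, kw = w.shape
    xp = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    OH = (H + 2 * padding - dilation * (kh - 1) - 1) // stride + 1
    OW = (W + 2 * padding - dilation * (kw - 1) - 1) // stride + 1
    out = np.zeros((B, Cout, OH, OW))
    cpg_out = Cout // groups
    for bi in range(B):
        for co in range(Cout):
            g = co // cpg_out
            for oy in range(OH):
                for ox in range(OW):
                    acc = 0.0
                    for ci in range(Cg):
                        for i in range(kh):
                            for j in range(kw):
                                acc += (w[co, ci, i, j] *
                                        xp[bi, g * Cg + ci,
                                           oy * stride + i * dilation,
                                           ox * stride + j * dilation])
                    out[bi, co, oy, ox] = acc
            if b is not None:
                out[bi, co] += b[co]
    return out


def linear_ref(x, layer):
    y = np.asarray(x, dtype=float) @ layer.weight.data.astype(float)
    if layer.bias is not None:
        y = y + layer.bias.data.astype(float)
    return y


def softmax_ref(x, axis=-1):
    e = np.exp(x - x.max(axis=axis, keepdims=True))
    return e / e.sum(axis=axis, keepdims=True)


def layernorm_ref(x, layer):
    mu = x.mean(axis=-1, keepdims=True)
    var = x.var(axis=-1, keepdims=True)
    xn = (x - mu) / np.sqrt(var + layer.eps)
    return xn * layer.weight.data + layer.bias.data


def unrolled_scan_ref(x, Abar, Bbar, Cmat, D):
    """Brute-force unrolled sum  y_t = Σ_{k≤t} C_t ∘ (Π_{j=k+1..t} Ā_j) B̄_k x_k + D x_t.

    Shapes: x (L, C); Abar/Bbar/Cmat (L, C, N) (broadcast per-position);
    D (C,).  Quadratic in L on purpose — an independent route to the same
    quantity the sequential recurrence computes.
    """
    L, C = x.shape
    N = Abar.shape[-1]
    y = np.zeros((L, C))
    for t in range(L):
        for k in range(t + 1):
            prod = np.ones((C, N))
            for j in range(k + 1, t + 1):
                prod = prod * Abar[j]
            y[t] += (Cmat[t] * prod * Bbar[k]).sum(axis=-1) * x[k]
        y[t] += D * x[t]
    return y


def haem_ref(x, haem):
    """Replay a HAEM forward (identity BN assumed) in straight-line NumPy."""
    B, C, H, W = x.shape
    ca = haem.channel_att

    def mlp(v):
        h = np.maximum(linear_ref(v, ca.fc0), 0.0)
        return linear_ref(h, ca.fc1)

    avg = x.mean(axis=(2, 3))
    mx = x.max(axis=(2, 3))
    mc = (mlp(avg) + mlp(mx)).reshape(B, C, 1, 1)

    sa = haem.spatial_att
    t = conv2d_ref(x, sa.reduce.weight.data, sa.reduce.bias.data)
    t = conv2d_ref(t, sa.dconv1.weight.data, sa.dconv1.bias.data,
                   padding=sa.dconv1.padding, dilation=sa.dconv1.dilation)
    t = conv2d_ref(t, sa.dconv2.weight.data, sa.dconv2.bias.data,
                   padding=sa.dconv2.padding, dilation=sa.dconv2.dilation)
    ms = conv2d_ref(t, sa.collapse.weight.data, sa.collapse.bias.data)

    s = mc + ms
    dw = conv2d_ref(s, haem.dwconv.weight.data, haem.dwconv.bias.data,
                    padding=1, groups=C)
    mh = 1.0 / (1.0 + np.exp(-(dw + s)))
    return x + mh * x


def cfm_ref(xe, xd, cfm):
    """Replay a CFM forward (identity BN assumed) in straight-line NumPy."""
    B, C, H, W = xd.shape
    cat = np.concatenate([xe, xd], axis=1)
    fused = conv2d_ref(cat, cfm.fuse_conv.weight.data, cfm.fuse_conv.bias.data,
                       padding=1)
    xe1 = np.maximum(fused, 0.0)

    L = H * W
    tok_d = xd.reshape(B, C, L).transpose(0, 2, 1)
    tok_e = xe1.reshape(B, C, L).transpose(0, 2, 1)
    at = cfm.attn
    q = tok_d @ at.wq.weight.data.astype(float)
    k = tok_e @ at.wk.weight.data.astype(float)
    v = tok_e @ at.wv.weight.data.astype(float)
    heads = []
    dk = at.dk
    for h in range(at.heads):
        sl = slice(h * dk, (h + 1) * dk)
        logits = q[..., sl] @ k[..., sl].transpose(0, 2, 1) / np.sqrt(dk)
        heads.append(softmax_ref(logits) @ v[..., sl])
    am = np.concatenate(heads, axis=-1) @ at.wo.weight.data.astype(float)

    r = am + tok_d
    ffn = np.maximum(linear_ref(r, cfm.ffn_fc1), 0.0)
    xf = r + linear_ref(ffn, cfm.ffn_fc2)
    return xf.transpose(0, 2, 1).reshape(B, C, H, W)


def ss2d_ref(x, mod):
    """Replay the learnable SS2D layer ((B, H, W, C) in/out) naively."""
    from mambaseg.ssm import scan_orders

    B, H, W, C = x.shape
    L = H * W
    tokens = x.reshape(B, L, C).astype(float)
    R, N = mod.dt_rank, mod.d_state
    out = np.zeros_like(tokens)
    for kdir, order in enumerate(scan_orders(H, W)):
        xp = mod.x_proj[kdir].weight.data.astype(float)
        dtw = mod.dt_proj[kdir].weight.data.astype(float)
        dtb = mod.dt_proj[kdir].bias.data.astype(float)
        A = -np.exp(getattr(mod, f"A_log_{kdir}").data.astype(float))
        D = getattr(mod, f"D_{kdir}").data.astype(float)
        for b in range(B):
            seq = tokens[b, order]                      # (L, C)
            proj = seq @ xp
            delta = np.logaddexp(0.0, proj[:, :R] @ dtw + dtb)   # softplus
            Bsel, Csel = proj[:, R:R + N], proj[:, R + N:]
            h = np.zeros((C, N))
            y = np.zeros((L, C))
            for t in range(L):
                Abar = np.exp(delta[t][:, None] * A)
                h = Abar * h + (delta[t] * seq[t])[:, None] * Bsel[t][None, :]
                y[t] = h @ Csel[t] + D * seq[t]
            out[b, order] += y
    return out.reshape(B, H, W, C)


def vss_block_ref(x, blk):
    """Straight-line replay of a VSS block on (B, H, W, C) tokens."""
    xn = layernorm_ref(x.astype(float), blk.norm)
    a = linear_ref(xn, blk.in_proj)
    di = a.shape[-1]
    a_cf = a.transpose(0, 3, 1, 2)
    a_cf = conv2d_ref(a_cf, blk.dwconv.weight.data, blk.dwconv.bias.data,
                      padding=1, groups=di)
    a = a_cf.transpose(0, 2, 3, 1)
    a = a * (1.0 / (1.0 + np.exp(-a)))                   # SiLU
    a = ss2d_ref(a, blk.ss2d)
    a = layernorm_ref(a, blk.out_norm)
    b = linear_ref(xn, blk.gate_proj)
    b = b * (1.0 / (1.0 + np.exp(-b)))
    return x + linear_ref(a * b, blk.out_proj)


def hd95_ref(A, B):
    """All-pairs distance matrix + percentile: the brute-force HD95."""
    A = np.asarray(A, float)
    B = np.asarray(B, float)
    d = np.sqrt(((A[:, None, :] - B[None, :, :]) ** 2).sum(-1))
    return max(np.percentile(d.min(axis=1), 95), np.percentile(d.min(axis=0), 95))
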