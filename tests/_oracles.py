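"""Independent reference implementations used only to check the package.

These are deliberately naive, loop-based transcriptions of the published
workflows, kept free of any code from ``mutclass`` so that agreement is
meaningful.
"""

import numpy as np


def cgf_reference(a: np.ndarray, d_cgf: float, n_cgf: int) -> list[int]:
    """Literal step-by-step gene filtering on a 0/1 gene × sample array.

    1. sort genes by descending row sum (ties by original index);
    2. walk the sorted list: each ungrouped gene opens a group, and every
       other still-ungrouped gene with Jaccard similarity strictly above
       ``d_cgf`` is assigned to it;
    3. from each group with at least ``n_cgf`` members take the
       ``n_cgf`` most frequent genes; return the sorted 1-based union.

    Genes that are never mutated are skipped in step 3 (they carry no
    frequency signal and must not ride in as singleton groups).
    """
    m = a.shape[0]
    sums = a.sum(axis=1).astype(int)
    order = sorted(range(m), key=lambda i: (-sums[i], i))
    group = [0] * m
    n_groups = 0
    for i in order:
        if group[i]:
            continue
        n_groups += 1
        group[i] = n_groups
        for j in order:
            if j == i or group[j]:
                continue
            union = int(np.sum(a[i] | a[j]))
            inter = int(np.sum(a[i] & a[j]))
            sim = inter / union if union else 0.0
            if sim > d_cgf:
                group[j] = n_groups
    g_out: list[int] = []
    for c in range(1, n_groups + 1):
        members = [i for i in range(m) if group[i] == c and sums[i] > 0]
        if len(members) >= n_cgf:
            top = sorted(members, key=lambda i: (-sums[i], i))[:n_cgf]
            g_out.extend(top)
    return sorted(i + 1 for i in g_out)


def grouping_reference(a: np.ndarray, d_cgf: float) -> list[int]:
    """Group ids (1-based, seed order) from the same literal walk."""
    m = a.shape[0]
    sums = a.sum(axis=1).astype(int)
    order = sorted(range(m), key=lambda i: (-sums[i], i))
    group = [0] * m
    n_groups = 0
    for i in order:
        if group[i]:
            continue
        n_groups += 1
        group[i] = n_groups
        for j in order:
            if j == i or group[j]:
                continue
            union = int(np.sum(a[i] | a[j]))
            inter = int(np.sum(a[i] & a[j]))
            if union and inter / union > d_cgf:
                group[j] = n_groups
    return group


def numeric_gradients(loss_fn, params_flat: np.ndarray, step: float = 1e-6):
    """Central-difference gradient of ``loss_fn`` over a flat vector."""
    grad = np.zeros_like(params_flat)
    for i in range(params_flat.size):
        up = params_flat.copy()
        down = params_flat.copy()
        up[i] += step
        down[i] -= step
        grad[i] = (loss_fn(up) - loss_fn(down)) / (2 * step)
    return grad


def mlp_forward_reference(x, weights, biases):
    """Plain-loop forward pass: ReLU on every layer except the last."""
    h = list(map(float, x))
    for l, (w, b) in enumerate(zip(weights, biases)):
        z = [sum(w[r][c] * h[c] for c in range(len(h))) + b[r]
             for r in range(len(b))]
        h = z if l == len(weights) - 1 else [max(v, 0.0) for v in z]
    return np.array(h)
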