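"""Independent brute-force oracles used to validate the fast paths.

These deliberately share no code with the implementation: matching is
exhaustive search over one-to-one assignments, and the rank-test p-value
is a full enumeration of group assignments.
"""

from itertools import combinations, permutations

from surgikit.evaluation import iou


def optimal_match_counts(dets, gts, threshold):
    """Exhaustive one-to-one matching per class: maximize TP, then total IoU.

    Returns {class_id: (tp, fp, fn)}.
    """
    out = {}
    class_ids = {d.class_id for d in dets} | {g.class_id for g in gts}
    for cid in class_ids:
        d = [x.box for x in dets if x.class_id == cid]
        g = [x.box for x in gts if x.class_id == cid]
        best_tp, best_iou_sum = 0, 0.0
        k_max = min(len(d), len(g))
        for k in range(k_max + 1):
            for d_idx in combinations(range(len(d)), k):
                for g_perm in permutations(range(len(g)), k):
                    pair_ious = [iou(d[i], g[j]) for i, j in zip(d_idx, g_perm)]
                    if any(v <= threshold for v in pair_ious):
                        continue
                    total = sum(pair_ious)
                    if k > best_tp or (k == best_tp and total > best_iou_sum):
                        best_tp, best_iou_sum = k, total
        out[cid] = (best_tp, len(d) - best_tp, len(g) - best_tp)
    return out


def permutation_p_two_sided(sample_a, sample_b):
    """Exact two-sided Mann-Whitney p by full enumeration (tie-free inputs).

    Counts assignments whose U deviates from the null mean at least as far
    as the observed U.
    """
    pooled = list(sample_a) + list(sample_b)
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free input"
    n_a = len(sample_a)
    mu = n_a * (len(pooled) - n_a) / 2.0

    def u_of(a_vals, b_vals):
        return sum(1 for x in a_vals for y in b_vals if x > y)

    u_obs = u_of(sample_a, sample_b)
    hits = total = 0
    for idx in combinations(range(len(pooled)), n_a):
        chosen = set(idx)
        a_vals = [pooled[i] for i in idx]
        b_vals = [pooled[i] for i in range(len(pooled)) if i not in chosen]
        if abs(u_of(a_vals, b_vals) - mu) >= abs(u_obs - mu):
            hits += 1
        total += 1
    return hits / total
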