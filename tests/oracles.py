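"""Independent reference implementations used only as test oracles.

These deliberately re-derive results through different code paths than the
package (explicit enumeration, dict-based recursion) so that agreement is a
meaningful check.
"""

from scipy import stats

FEATURE_COUNT = 4


def hypergeom_two_sided(a, b, c, d):
    """Two-sided Fisher p by full hypergeometric enumeration of all 2x2
    tables with the observed margins."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    rv = stats.hypergeom(n, r1, c1)
    p_obs = rv.pmf(a)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = rv.pmf(x)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return min(1.0, total)


def oracle_gini(labels):
    n = len(labels)
    if n == 0:
        return 0.0
    p = sum(1 for l in labels if l == "DCB") / n
    return 2 * p * (1 - p)


def oracle_tree(rows, labels, depth):
    """Dict-based CART with the same conventions as the package: Gini,
    smallest-feature tie-break, leaf tie -> NDB, zero-gain fallback split."""
    n_dcb = sum(1 for l in labels if l == "DCB")
    pred = "DCB" if n_dcb > len(labels) - n_dcb else "NDB"
    if depth == 0 or n_dcb in (0, len(labels)):
        return pred
    best = None
    parent = oracle_gini(labels)
    for j in range(FEATURE_COUNT):
        left = [l for r, l in zip(rows, labels) if not r[j]]
        right = [l for r, l in zip(rows, labels) if r[j]]
        if not left or not right:
            continue
        child = (len(left) * oracle_gini(left)
                 + len(right) * oracle_gini(right)) / len(labels)
        if parent - child > 1e-12 and (best is None or parent - child > best[0] + 1e-12):
            best = (parent - child, j)
    if best is None:
        for j in range(FEATURE_COUNT):
            if len({r[j] for r in rows}) == 2:
                best = (0.0, j)
                break
    if best is None:
        return pred
    j = best[1]
    return {
        False: oracle_tree([r for r in rows if not r[j]],
                           [l for r, l in zip(rows, labels) if not r[j]], depth - 1),
        True: oracle_tree([r for r in rows if r[j]],
                          [l for r, l in zip(rows, labels) if r[j]], depth - 1),
        "feature": j,
    }


def oracle_predict(tree, row):
    while isinstance(tree, dict):
        tree = tree[bool(row[tree["feature"]])]
    return tree


def oracle_loo_f1(rows, labels, depth):
    preds = []
    for i in range(len(rows)):
        t = oracle_tree(rows[:i] + rows[i + 1:], labels[:i] + labels[i + 1:], depth)
        preds.append(oracle_predict(t, rows[i]))
    tp = sum(1 for p, l in zip(preds, labels) if p == "DCB" and l == "DCB")
    pp = sum(1 for p in preds if p == "DCB")
    ap = sum(1 for l in labels if l == "DCB")
    if pp == 0:
        return 1.0 if ap == 0 else 0.0
    if tp == 0:
        return 0.0
    prec, rec = tp / pp, tp / ap
    return 2 * prec * rec / (prec + rec)


def brute_force_windows(context, pos, lengths=(8, 9, 10, 11)):
    """All substrings of the given lengths containing the 1-based mutant
    position, deduplicated keeping first occurrence."""
    out, seen = [], set()
    for length in sorted(lengths):
        for offset in range(len(context) - length + 1):
            if offset < pos <= offset + length:
                pep = context[offset:offset + length]
                if pep not in seen:
                    seen.add(pep)
                    out.append((pep, offset))
    return out
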