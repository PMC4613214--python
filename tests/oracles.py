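"""Independent brute-force reference implementations.

Deliberately written as plain double loops over genes, pairs, samples
and conditions using :mod:`statistics`, independent of the package's
vectorized code paths, so they can serve as oracles.
"""

import itertools
import math
import statistics


def brute_msd(cq: dict) -> dict:
    """ΔCt mean-SD per gene from a gene -> list-of-Cq mapping."""
    genes = sorted(cq)
    out = {}
    for g in genes:
        sds = []
        for h in genes:
            if h == g:
                continue
            diffs = [a - b for a, b in zip(cq[g], cq[h])]
            sds.append(statistics.stdev(diffs))
        out[g] = sum(sds) / len(sds)
    return out


def brute_quantities(cq: dict, eff: dict) -> dict:
    out = {}
    for g, values in cq.items():
        lo = min(values)
        out[g] = [eff[g] ** (-(v - lo)) for v in values]
    return out


def brute_genorm_m(q: dict) -> dict:
    """geNorm M per gene from a gene -> list-of-quantities mapping."""
    genes = sorted(q)
    out = {}
    for g in genes:
        vs = []
        for h in genes:
            if h == g:
                continue
            ratios = [math.log2(a / b) for a, b in zip(q[g], q[h])]
            vs.append(statistics.stdev(ratios))
        out[g] = sum(vs) / len(vs)
    return out


def brute_v_series(q: dict, ranked: list) -> dict:
    """geNorm V_n/n+1 along a ranked gene list."""
    n_samples = len(next(iter(q.values())))

    def log_nf(genes, s):
        return sum(math.log2(q[g][s]) for g in genes) / len(genes)

    out = {}
    for n in range(2, len(ranked)):
        diffs = [
            log_nf(ranked[:n], s) - log_nf(ranked[: n + 1], s)
            for s in range(n_samples)
        ]
        out[n] = statistics.stdev(diffs)
    return out


def brute_graynorm(cq: dict, eff: dict, conditions: list, control) -> dict:
    """GrayNorm scores for every combination.

    ``cq`` maps gene -> list of Cq; ``conditions`` gives the condition
    label of each list position.  Returns combination-tuple ->
    (condition-mean 1/NF dict, cv_inter %, cumulative deviation).
    """
    genes = sorted(cq)
    cond_set = list(dict.fromkeys(conditions))
    calibrated = {}
    for g in genes:
        ctrl = [v for v, c in zip(cq[g], conditions) if c == control]
        mean_ctrl = sum(ctrl) / len(ctrl)
        calibrated[g] = [eff[g] ** (mean_ctrl - v) for v in cq[g]]
    out = {}
    for size in range(1, len(genes) + 1):
        for combo in itertools.combinations(genes, size):
            inv_nf = []
            for s in range(len(conditions)):
                prod = 1.0
                for g in combo:
                    prod *= calibrated[g][s]
                inv_nf.append(1.0 / (prod ** (1.0 / size)))
            means = {}
            for c in cond_set:
                vals = [v for v, cc in zip(inv_nf, conditions) if cc == c]
                means[c] = sum(vals) / len(vals)
            mvals = list(means.values())
            cv = 100.0 * statistics.stdev(mvals) / statistics.mean(mvals)
            cumdev = sum(abs(means[c] - 1.0) for c in cond_set if c != control)
            out[combo] = (means, cv, cumdev)
    return out


def brute_footrule_optimum(lists: list) -> float:
    """Minimum total footrule over all permutations (small item sets)."""
    items = sorted(lists[0])
    best = math.inf
    for perm in itertools.permutations(items):
        pos = {g: i for i, g in enumerate(perm)}
        total = 0
        for l in lists:
            total += sum(abs(pos[g] - i) for i, g in enumerate(l))
        best = min(best, total)
    return float(best)
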