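"""Independent reference implementations shared by the test modules."""

import itertools

from imurehab.evaluation import ConfusionCounts, _end_valid, _start_valid


def brute_force_match(predicted, manual, tol):
    """Exhaustive best one-to-one assignment of boundary points.

    Enumerates every injective mapping of manual points to predicted points
    and keeps the one with the most valid pairs — the ground truth the
    greedy nearest-first matcher must reproduce.
    """
    tb, ta = tol.t_before * tol.sample_rate, tol.t_after * tol.sample_rate
    m_starts = manual.starts().astype(float)
    m_ends = manual.ends().astype(float)

    def best(points, anchors, valid):
        n_m = len(anchors)
        best_tp = 0
        for k in range(min(n_m, len(points)), -1, -1):
            if k <= best_tp:
                break
            found = False
            for manual_subset in itertools.combinations(range(n_m), k):
                for pred_perm in itertools.permutations(range(len(points)), k):
                    if all(
                        valid(points[j], m)
                        for m, j in zip(manual_subset, pred_perm)
                    ):
                        found = True
                        break
                if found:
                    break
            if found:
                best_tp = k
                break
        return ConfusionCounts(
            tp=best_tp, fp=len(points) - best_tp, fn=n_m - best_tp
        )

    c_start = best(
        predicted.starts().astype(float), m_starts,
        lambda p, k: _start_valid(p, k, m_starts, m_ends, tb, ta),
    )
    c_end = best(
        predicted.ends().astype(float), m_ends,
        lambda p, k: _end_valid(p, k, m_starts, m_ends, tb, ta),
    )
    return c_start + c_end
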