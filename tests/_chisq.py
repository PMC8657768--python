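"""Shared goodness-of-fit helper for walk-transition tests."""

import numpy as np
from scipy import stats

from ppirank.walks import node2vec_transition_weights


def pooled_transition_chi_square(graph, corpus, p, q):
    """Chi-square statistic and 99th-percentile threshold for observed
    (prev, cur) -> next transition counts against the exact biased
    transition distribution.  Cells with expected count < 5 are pooled
    within each conditional distribution (standard small-cell fix)."""
    trans = {}
    for walk in corpus.walks:
        for t in range(1, len(walk) - 1):
            key = (walk[t - 1], walk[t])
            nbrs = graph.adjacency[walk[t]]
            if key not in trans:
                trans[key] = np.zeros(len(nbrs))
            trans[key][int(np.searchsorted(nbrs, walk[t + 1]))] += 1
    stat, dof = 0.0, 0
    for (prev, cur), obs in trans.items():
        w = node2vec_transition_weights(prev, cur, graph, p, q)
        exp = w / w.sum() * obs.sum()
        keep = exp >= 5
        if keep.sum() < len(exp):
            # Cochran's rule: every cell, including the pooled remainder,
            # needs expected count >= 5; a small remainder folds into the
            # smallest retained cell rather than standing alone
            obs_rest, exp_rest = obs[~keep].sum(), exp[~keep].sum()
            obs, exp = obs[keep], exp[keep]
            if exp_rest >= 5:
                obs = np.r_[obs, obs_rest]
                exp = np.r_[exp, exp_rest]
            elif len(exp):
                i = int(np.argmin(exp))
                obs[i] += obs_rest
                exp[i] += exp_rest
        if len(obs) < 2:
            continue
        stat += float(np.sum((obs - exp) ** 2 / exp))
        dof += len(obs) - 1
    return stat, float(stats.chi2.ppf(0.99, dof))
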