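"""Brute-force ROH oracle: test every subinterval against every rule.

Independent of the package's caller: validity of all O(L^2) subintervals is
evaluated directly with prefix sums and running maxima, then reduced to the
maximal intervals (no single-SNP extension stays valid).
"""

import numpy as np

from pigpopgen.genotype_io import MISSING


def brute_force_roh(calls, pos, params, class_index):
    """All maximal valid (start_bp, end_bp, n_snps) triples, sorted."""
    min_len, allowed_missing = params.classes[class_index]
    L = len(pos)
    pos = np.asarray(pos, dtype=np.int64)
    bad = ~np.isin(calls, (0, 2, MISSING))          # heterozygote or invalid
    miss = calls == MISSING
    cbad = np.concatenate(([0], np.cumsum(bad)))
    cmiss = np.concatenate(([0], np.cumsum(miss)))
    gaps = np.diff(pos)

    s_idx = np.arange(L)[:, None]
    e_idx = np.arange(L)[None, :]
    n = e_idx - s_idx + 1
    length = (pos[None, :] - pos[:, None]) / 1e6
    # running max gap within (s..e): row-wise cummax of the gap sequence
    gap_ok = np.ones((L, L), dtype=bool)
    if L > 1:
        run = np.zeros((L, L))
        for s in range(L):
            run[s, s + 1:] = np.maximum.accumulate(gaps[s:])
        gap_ok = run <= params.max_gap_mb * 1e6

    with np.errstate(divide="ignore", invalid="ignore"):
        valid = ((cbad[e_idx + 1] - cbad[s_idx]) == 0) \
            & ((cmiss[e_idx + 1] - cmiss[s_idx]) <= allowed_missing) \
            & (n >= params.min_snps) & (length >= min_len) \
            & gap_ok & (length / n <= params.density_mb_per_snp) \
            & (e_idx >= s_idx)

    ext_left = np.zeros_like(valid)
    ext_left[1:, :] = valid[:-1, :]
    ext_right = np.zeros_like(valid)
    ext_right[:, :-1] = valid[:, 1:]
    maximal = valid & ~ext_left & ~ext_right
    return sorted((int(pos[s]), int(pos[e]), int(e - s + 1))
                  for s, e in zip(*np.nonzero(maximal)))
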