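"""Independent brute-force oracles used by the test suite.

These deliberately avoid the seeded/heuristic code paths of the package:
the RCM oracle walks every diagonal of the full comparison matrix.
"""

from circflow._util import revcomp


def brute_force_rcms(up, down, min_len=21):
    """O(n*m) diagonal walk: every maximal exact match of ``up`` against
    revcomp(``down``), as (up_start, up_end, down_start, down_end) with the
    downstream span in forward-strand coordinates."""
    u, v = up.upper(), revcomp(down.upper())
    hits = []
    for d in range(-(len(v) - 1), len(u)):
        i = max(0, d)
        run = 0
        while True:
            j = i - d
            inside = i < len(u) and j < len(v)
            ok = inside and u[i] == v[j] and u[i] != "N"
            if ok:
                run += 1
            else:
                if run >= min_len:
                    hits.append((i - run, i, len(down) - j, len(down) - (j - run)))
                run = 0
            if not inside:
                break
            i += 1
    return sorted(hits)
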