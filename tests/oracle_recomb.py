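"""Independent brute-force oracle for recombination counting.

Enumerates every assignment of heterozygous loci to ordered haplotype
states (a|b vs b|a) and returns the minimum number of haplotype-origin
switches between consecutive non-missing markers.  Exponential in the
number of H calls — only usable on short sequences — and deliberately
separate from the production transition-cost implementation.
"""

from itertools import product

# Possible ordered (hap1, hap2) parental-origin states per call.
_STATES = {
    "A": [(0, 0)],
    "B": [(1, 1)],
    "H": [(0, 1), (1, 0)],
}


def min_switches_single_chrom(calls):
    """Minimal haplotype switches for one chromosome of ABH- calls."""
    called = [c for c in calls if c != "-"]
    if len(called) < 2:
        return 0
    choices = [_STATES[c] for c in called]
    best = None
    for assignment in product(*choices):
        cost = sum(
            (s1[0] != s2[0]) + (s1[1] != s2[1])
            for s1, s2 in zip(assignment, assignment[1:])
        )
        best = cost if best is None else min(best, cost)
    return best


def min_switches(calls, block_sizes):
    """Sum of per-chromosome minimal switches; blocks partition the calls."""
    total, start = 0, 0
    for size in block_sizes:
        total += min_switches_single_chrom(calls[start:start + size])
        start += size
    return total
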