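"""Independent brute-force oracles shared by the test modules."""

import itertools


def oracle_events(isoforms):
    """Plain O(n^2) re-derivation of the AS event rules, kept separate from
    the implementation under test."""
    found = set()
    strand = isoforms[0].strand
    for a, b in itertools.permutations(isoforms, 2):
        for ex in a.exons:
            for it in b.introns:
                if ex[0] <= it[0] and it[1] <= ex[1]:
                    found.add(("IR", it))
        for ex in a.exons[1:-1]:
            for it in b.introns:
                if it[0] <= ex[0] and ex[1] <= it[1]:
                    found.add(("ES", ex))
        for it in b.introns:
            for pos in (a.start, a.end):
                if it[0] < pos < it[1]:
                    found.add(("OTHER", it))
    for a, b in itertools.combinations(isoforms, 2):
        for ia in a.introns:
            for ib in b.introns:
                if ia == ib:
                    continue
                shared_start = ia[0] == ib[0]
                shared_end = ia[1] == ib[1]
                if shared_start == shared_end:
                    continue
                if shared_start:
                    lo, hi = sorted((ia[1], ib[1]))
                    owner = a if ia[1] < ib[1] else b
                    typ = "A3SS" if strand == "+" else "A5SS"
                else:
                    lo, hi = sorted((ia[0], ib[0]))
                    owner = a if ia[0] > ib[0] else b
                    typ = "A5SS" if strand == "+" else "A3SS"
                if any(lo <= s and e <= hi for s, e in owner.exons):
                    continue
                found.add((typ, (lo, hi)))
    pair_diff = any(
        set(a.introns) != set(b.introns) for a, b in itertools.combinations(isoforms, 2)
    )
    if not found and pair_diff:
        for a, b in itertools.combinations(isoforms, 2):
            diff = sorted(set(a.introns) ^ set(b.introns))
            if diff:
                found.add(("OTHER", (min(s for s, _ in diff), max(e for _, e in diff))))
    return found
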