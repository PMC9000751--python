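"""Independent brute-force oracles used by the test suite only."""


def scan_displacements(ranked, members):
    """O(M) full scan of C_i/N − i/M — the oracle for the O(N) shortcut."""
    members = set(members)
    m = len(ranked)
    n = len(members & set(ranked))
    c = 0
    values = []
    for i, key in enumerate(ranked, start=1):
        if key in members:
            c += 1
        values.append(c / n - i / m)
    return max(values), min(values)
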