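"""Independent reference implementations used only by the tests.

These deliberately do not reuse the package's DP code paths: the full DP
oracle is an unbanded three-state Gotoh local aligner written from the
recurrences, and the overlap oracle is a literal shifted-set intersection.
Tie conventions match the package contract (M over D over I over stop;
gap-open over gap-extend; first best cell scanning rows then columns).
"""

from __future__ import annotations


def brute_force_overlap(offsets: list[int], span: int, d: int) -> int:
    """ovl(d) by explicit set intersection of two pattern placements."""
    shift = span - d
    first = set(offsets)
    second = {x + shift for x in offsets}
    return len(first & second)


def full_dp_local(read: str, ref: str, params) -> tuple[int, str]:
    """Unbanded affine-gap local alignment; returns (score, CIGAR).

    ``params`` provides substitution(read_base, ref_base), gap_open and
    gap_extend (positive magnitudes); a gap of length L costs
    open + extend * L.  Soft-clips unaligned read ends.
    """
    n, m = len(read), len(ref)
    NEG = float("-inf")
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    # pointers: H: 0 stop, 1 diag, 2 from E, 3 from F; E/F: 0 open, 1 extend
    HP = [[0] * (m + 1) for _ in range(n + 1)]
    EP = [[0] * (m + 1) for _ in range(n + 1)]
    FP = [[0] * (m + 1) for _ in range(n + 1)]
    go, ge = params.gap_open + params.gap_extend, params.gap_extend

    best, bi, bj = 0.0, 0, 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            e_open, e_ext = H[i][j - 1] - go, E[i][j - 1] - ge
            if e_open >= e_ext:
                E[i][j], EP[i][j] = e_open, 0
            else:
                E[i][j], EP[i][j] = e_ext, 1
            f_open, f_ext = H[i - 1][j] - go, F[i - 1][j] - ge
            if f_open >= f_ext:
                F[i][j], FP[i][j] = f_open, 0
            else:
                F[i][j], FP[i][j] = f_ext, 1
            diag = H[i - 1][j - 1] + params.substitution(read[i - 1], ref[j - 1])
            h, p = diag, 1
            if E[i][j] > h:
                h, p = E[i][j], 2
            if F[i][j] > h:
                h, p = F[i][j], 3
            if h <= 0:
                h, p = 0.0, 0
            H[i][j], HP[i][j] = h, p
            if h > best:
                best, bi, bj = h, i, j

    if best <= 0:
        return 0, f"{n}S" if n else ""

    ops = []
    i, j, state = bi, bj, "H"
    while True:
        if state == "H":
            p = HP[i][j]
            if p == 0:
                break
            if p == 1:
                ops.append("M")
                i, j = i - 1, j - 1
            elif p == 2:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            ops.append("D")
            if EP[i][j] == 0:
                state = "H"
            j -= 1
        else:
            ops.append("I")
            if FP[i][j] == 0:
                state = "H"
            i -= 1
    ops.reverse()

    parts = []
    if i:
        parts.append(f"{i}S")
    run_op, run_len = "", 0
    for op in ops:
        if op == run_op:
            run_len += 1
        else:
            if run_op:
                parts.append(f"{run_len}{run_op}")
            run_op, run_len = op, 1
    if run_op:
        parts.append(f"{run_len}{run_op}")
    if n - bi:
        parts.append(f"{n - bi}S")
    return int(best), "".join(parts)


def mutate(seq: str, rate: float, rng) -> str:
    """Substitute each base independently at ``rate`` (test helper)."""
    out = []
    for ch in seq:
        if rng.random() < rate:
            out.append("ACGT".replace(ch, "")[rng.integers(0, 3)])
        else:
            out.append(ch)
    return "".join(out)
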