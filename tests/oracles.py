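"""Independent brute-force oracles used to validate the package.

Everything here is written from first principles (naive dynamic programs,
exhaustive scans), deliberately sharing no code with the implementations
it checks.
"""

from __future__ import annotations

from Bio.Align import substitution_matrices
from Bio.Data import CodonTable

_B62 = substitution_matrices.load("BLOSUM62")
_TABLE = CodonTable.unambiguous_dna_by_id[1]
STOPS = {"TAA", "TAG", "TGA"}
STARTS = {"ATG", "GTG", "TTG"}

NEG = float("-inf")


def aa_score(a: str, b: str) -> float:
    try:
        return float(_B62[a][b])
    except (KeyError, IndexError):
        return float(min(min(row) for row in _B62))


def nt_score(a: str, b: str, match=2.0, mismatch=-3.0) -> float:
    if a in "ACGT" and a == b:
        return match
    return mismatch


def naive_global_align(a, b, alphabet="nt", match=2.0, mismatch=-3.0,
                       gap_open=None, gap_extend=None):
    """Gotoh global alignment by explicit table-filling, state preference
    substitution > gap-in-b > gap-in-a at every tie.  Returns
    (score, identity, mismatches, aligned_positions)."""
    if gap_open is None:
        gap_open = 10.0 if alphabet == "nt" else 11.0
    if gap_extend is None:
        gap_extend = 4.0 if alphabet == "nt" else 1.0
    open1 = gap_open + gap_extend
    ext = gap_extend
    sub = (lambda x, y: nt_score(x, y, match, mismatch)) if alphabet == "nt" else aa_score
    a, b = a.upper(), b.upper()
    n, m = len(a), len(b)

    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    pM = [[0] * (m + 1) for _ in range(n + 1)]
    pX = [[0] * (m + 1) for _ in range(n + 1)]
    pY = [[0] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = -open1 - (i - 1) * ext
        pX[i][0] = 1
    for j in range(1, m + 1):
        Y[0][j] = -open1 - (j - 1) * ext
        pY[0][j] = 1
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            prev = (M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            best = max(prev)
            pM[i][j] = prev.index(best)
            M[i][j] = sub(a[i - 1], b[j - 1]) + best
            fm, fx = M[i - 1][j] - open1, X[i - 1][j] - ext
            X[i][j] = max(fm, fx)
            pX[i][j] = 0 if fm >= fx else 1
            gm, gy = M[i][j - 1] - open1, Y[i][j - 1] - ext
            Y[i][j] = max(gm, gy)
            pY[i][j] = 0 if gm >= gy else 1

    finals = (M[n][m], X[n][m], Y[n][m])
    state = finals.index(max(finals))
    score = finals[state]
    i, j = n, m
    ident = mism = aligned = 0
    while i > 0 or j > 0:
        if state == 0:
            same = a[i - 1] == b[j - 1] and (alphabet == "aa" or a[i - 1] in "ACGT")
            aligned += 1
            if same:
                ident += 1
            else:
                mism += 1
            state = pM[i][j]
            i, j = i - 1, j - 1
        elif state == 1:
            state = 1 if pX[i][j] else 0
            i -= 1
        else:
            state = 2 if pY[i][j] else 0
            j -= 1
    identity = ident / aligned if aligned else 0.0
    return score, identity, mism, aligned


def sw_score(a: str, b: str, gap_open=11.0, gap_extend=1.0) -> float:
    """Smith-Waterman best local score, affine gaps, BLOSUM62 - full
    tables, no cleverness."""
    open1 = gap_open + gap_extend
    ext = gap_extend
    n, m = len(a), len(b)
    M = [[0.0] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        ai = a[i - 1]
        Mi, Mi1 = M[i], M[i - 1]
        Xi, Xi1 = X[i], X[i - 1]
        Yi, Yi1 = Y[i], Y[i - 1]
        for j in range(1, m + 1):
            Xi[j] = max(Mi1[j] - open1, Xi1[j] - ext)
            Yi[j] = max(Mi[j - 1] - open1, Yi[j - 1] - ext)
            cand = aa_score(ai, b[j - 1]) + max(Mi1[j - 1], Xi1[j - 1], Yi1[j - 1])
            Mi[j] = max(0.0, cand)
            if Mi[j] > best:
                best = Mi[j]
    return best


def translate_codon(codon: str) -> str:
    if codon in STOPS:
        return "*"
    return _TABLE.forward_table.get(codon, "X")


def six_frames_brute(seq: str) -> dict[int, str]:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    rc = "".join(comp.get(c, "N") for c in reversed(seq.upper()))
    out = {}
    for off in range(3):
        for frame, src in ((off + 1, seq.upper()), (-(off + 1), rc)):
            prot = []
            for i in range(off, len(src) - 2, 3):
                prot.append(translate_codon(src[i : i + 3]))
            out[frame] = "".join(prot)
    return out


def orfs_brute(seq: str, min_aa: int, starts=STARTS):
    """Exhaustive per-frame ORF enumeration mirroring the documented
    contract: internal stop-bounded segments from their first start codon,
    edge segments with partial flags.  Returns a set of
    (start, end, strand, partial5, partial3, protein)."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    L = len(seq)
    seq = seq.upper()
    rc = "".join(comp.get(c, "N") for c in reversed(seq))
    found = set()
    for strand, src in (("+", seq), ("-", rc)):
        for off in range(3):
            codons = [src[i : i + 3] for i in range(off, len(src) - 2, 3)]
            stops = [k for k, c in enumerate(codons) if c in STOPS]
            bounds = [-1] + stops + [len(codons)]
            for bi in range(len(bounds) - 1):
                lo, hi = bounds[bi] + 1, bounds[bi + 1]
                has_stop = bounds[bi + 1] < len(codons)
                if bi == 0:
                    c0, p5 = 0, True
                else:
                    c0 = None
                    for k in range(lo, hi):
                        if codons[k] in starts:
                            c0 = k
                            break
                    if c0 is None:
                        continue
                    p5 = False
                prot = "".join(translate_codon(c) for c in codons[c0:hi])
                if not prot or len(prot) < min_aa:
                    continue
                p3 = not has_stop
                s_loc = off + 3 * c0
                e_loc = off + 3 * (hi + (1 if has_stop else 0))
                if strand == "+":
                    s, e = s_loc, e_loc
                else:
                    s, e = L - e_loc, L - s_loc
                found.add((s, e, strand, p5, p3, prot))
    return found


def components_brute(names, edge_fn):
    """Connected components by repeated sweeps (no library)."""
    comp = {n: n for n in names}
    changed = True
    while changed:
        changed = False
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                if edge_fn(a, b):
                    ra, rb = comp[a], comp[b]
                    if ra != rb:
                        target = min(ra, rb)
                        for k, v in comp.items():
                            if v in (ra, rb):
                                comp[k] = target
                        changed = True
    return len(set(comp.values()))
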