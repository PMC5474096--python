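"""Independent oracles used to cross-check the implementation.

These are deliberately coded from the written decision rules and from
first principles, without importing the implementation's logic, so that
agreement between the two routes is meaningful.
"""

from __future__ import annotations


def rule_table_category(
    n_arch: int,
    n_phage: int,
    n_cell: int,
    n_euk: int,
    bit_arch: float,
    bit_phage: float,
) -> object:
    """Truth-table re-statement of the three category rules.

    Default thresholds only: majority 2/3 (strict), minority 1/3
    (inclusive), quality floor 75 (strict), archaeal-vs-phage bit
    comparison strict for categories 1/3.  Fraction comparisons use
    cross-multiplication so the 1/3 and 2/3 boundaries are exact.
    Returns 1, 2, 3 or None.
    """
    n_annot = n_arch + n_phage + n_cell + n_euk
    denom = n_arch + n_phage + n_cell  # eukaryotic-virus genes excluded
    majority = denom > 0 and 3 * n_arch > 2 * denom
    minority = denom > 0 and 3 * n_arch >= denom and 3 * n_arch <= 2 * denom
    quality = bit_arch > 75.0
    beats_phage = bit_arch > bit_phage

    if n_annot >= 3 and majority and quality and beats_phage:
        return 1
    if 1 <= n_annot <= 2 and n_arch == n_annot and quality:
        return 1
    if n_annot >= 3 and majority and quality and not beats_phage:
        return 2
    if n_annot >= 3 and minority and quality and beats_phage:
        return 3
    return None


def edlib_ani(seq_a: str, seq_b: str) -> float:
    """Global-alignment ANI (%) via edlib's edit-distance DP, from the CIGAR.

    Identities are '=' columns over all alignment columns; N never counts
    as an identity (edlib treats it as an ordinary mismatching letter).
    """
    import re

    import edlib

    result = edlib.align(seq_a, seq_b, task="path", mode="NW")
    matches = 0
    columns = 0
    for count, op in re.findall(r"(\d+)([=XIDM])", result["cigar"]):
        n = int(count)
        columns += n
        if op == "=":
            matches += n
    return 100.0 * matches / columns


def brute_force_mantel_p(d1, d2, r_obs: float) -> float:
    """Exhaustive-permutation one-tailed Mantel p-value for tiny matrices."""
    import itertools
    import math

    import numpy as np

    n = d1.shape[0]
    iu = np.triu_indices(n, k=1)
    x = d1[iu]
    x = x - x.mean()
    sx = math.sqrt((x * x).sum())
    count = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        pm = np.asarray(perm)
        y = d2[np.ix_(pm, pm)][iu]
        y = y - y.mean()
        r = (x * y).sum() / (sx * math.sqrt((y * y).sum()))
        total += 1
        if r >= r_obs - 1e-12:
            count += 1
    return count / total
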