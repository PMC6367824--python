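"""Independent brute-force oracle for the points-based profile score.

Deliberately written as a literal walk over explicit band-edge lists
(no shared code with the package implementation) so it can serve as a
cross-check in tests.
"""

from bisect import bisect_left

_ENERGY_EDGES_KJ = [335, 670, 1005, 1340, 1675, 2010, 2345, 2680, 3015, 3350]
_SATFAT_EDGES = [1, 2, 3, 4, 5, 6, 7, 8, 9, 10]
_SUGARS_EDGES = [4.5, 9.0, 13.5, 18.0, 22.5, 27.0, 31.5, 36.0, 40.5, 45.0]
_SODIUM_EDGES = [90, 180, 270, 360, 450, 540, 630, 720, 810, 900]
_PROTEIN_EDGES = [1.6, 3.2, 4.8, 6.4, 8.0]
_FIBRE_EDGES = [0.9, 1.9, 2.8, 3.7, 4.7]
_THRESHOLDS = {1: 1, 2: 4, 3: 28}


def _points(value, edges):
    # number of edges strictly below the value
    i = bisect_left(edges, value)
    while i < len(edges) and value > edges[i]:
        i += 1
    # bisect_left gives first index with edge >= value; points = count(edge < value)
    return sum(1 for e in edges if value > e)


def oracle_score(energy_kcal, satfat_g, sugars_g, sodium_mg, protein_g,
                 fibre_g, fvnl_percent, category):
    kj = energy_kcal * 4.184
    baseline = (
        _points(kj, _ENERGY_EDGES_KJ)
        + _points(satfat_g, _SATFAT_EDGES)
        + _points(sugars_g, _SUGARS_EDGES)
        + _points(sodium_mg, _SODIUM_EDGES)
    )
    if fvnl_percent > 80:
        v = 5
    elif fvnl_percent > 60:
        v = 2
    elif fvnl_percent > 40:
        v = 1
    else:
        v = 0
    p = _points(protein_g, _PROTEIN_EDGES)
    if baseline >= 13 and v < 5:
        p = 0
    f = _points(fibre_g, _FIBRE_EDGES)
    score = baseline - (v + p + f)
    return score, score < _THRESHOLDS[category]
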