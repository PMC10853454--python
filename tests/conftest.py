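import numpy as np
import pytest

import shedmap as sm

RESIDUES = "ACDEFGHIKLMNPQRSTVWY"
FOUR_PROTEASES = ["trypsinP", "lysC", "chymotrypsin", "aspN"]


@pytest.fixture
def registry():
    return dict(sm.DEFAULT_PROTEASES)


@pytest.fixture
def four_proteases(registry):
    return [registry[name] for name in FOUR_PROTEASES]


@pytest.fixture
def trypsin(registry):
    return registry["trypsinP"]


def random_protein(rng, length, protein_id="X"):
    return sm.ProteinRecord(protein_id, "".join(rng.choice(list(RESIDUES), size=length)))


def brute_force_cut_points(protein, protease):
    """Independent scan of every bond against the specificity rule."""
    seq = protein.sequence
    points = []
    for p in range(1, len(seq)):
        if protease.side.value == "after":
            if seq[p - 1] in protease.cut_residues and seq[p] not in protease.blocked_next:
                points.append(p)
        else:
            if seq[p] in protease.cut_residues:
                points.append(p)
    return points


def brute_force_semi(protein, protease, missed, length_range):
    """Exhaustive substring enumeration filtered by the terminus test."""
    cuts = set(brute_force_cut_points(protein, protease))
    n = len(protein)
    lo, hi = length_range
    out = set()
    for s in range(1, n + 1):
        for e in range(s, n + 1):
            if not (lo <= e - s + 1 <= hi):
                continue
            if sum(1 for c in cuts if s <= c < e) > missed:
                continue
            n_ok = s == 1 or (s - 1) in cuts
            c_ok = e == n or e in cuts
            if n_ok or c_ok:
                out.add((s, e))
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(20240501)
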