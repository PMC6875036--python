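"""Synthetic curated reference transposases with annotated catalytic triads.

Real curated Tc1/mariner references (Passport-, Prince-, Quetzal-,
Sleeping-Beauty-like proteins) are not redistributed here; instead a small
deterministic set of synthetic reference transposases is generated from a
common synthetic ancestor protein, one per family architecture (DD34E,
DD34D, DD37E). Each carries annotated D/D/E(D) triad columns, a GRPR box
in the N-terminal DNA-binding region, and family-specific triad spacing,
which is all `detect_triad` needs to transfer annotation onto a query.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

from .annotation import CatalyticTriad, ReferenceTransposase

__all__ = ["default_references", "build_protein", "ancestor_layout"]

_AA20 = "ACDEFGHIKLMNPQRSTVWY"
# layout of the synthetic transposase scaffold (346 aa at spacer2=36):
# [N-terminal DBD, 150 aa, GRPR at 60] [D1] [linker, 92 aa] [D2]
# [spacer2 aa] [E/D] [C-terminal tail]
_N_TERM_LEN = 150
_GRPR_AT = 60
_LINKER_LEN = 92
_ANCESTOR_SEED = 814551


def ancestor_layout(orf_aa: int = 346, spacer2: int = 36) -> dict[str, int]:
    """Triad coordinates implied by the scaffold for a given total length."""
    d1 = _N_TERM_LEN
    d2 = d1 + 1 + _LINKER_LEN
    e3 = d2 + 1 + spacer2
    c_term = orf_aa - (e3 + 1)
    if c_term < 10:
        raise ValueError("ORF too short for the transposase scaffold")
    return {"d1": d1, "d2": d2, "e3": e3, "c_term": c_term}


@lru_cache(maxsize=1)
def _ancestor_pools() -> dict[str, str]:
    rng = np.random.default_rng(_ANCESTOR_SEED)
    aa = np.array(list(_AA20))

    def draw(n: int) -> str:
        return "".join(rng.choice(aa, size=n))

    n_term = list(draw(_N_TERM_LEN))
    n_term[0] = "M"
    n_term[_GRPR_AT:_GRPR_AT + 4] = list("GRPR")
    return {
        "n_term": "".join(n_term),
        "linker": draw(_LINKER_LEN),
        "spacer_pool": draw(64),
        "c_term_pool": draw(200),
    }


def build_protein(spacer2: int = 36, third_residue: str = "E",
                  orf_aa: int = 346, mutate_frac: float = 0.0,
                  rng: np.random.Generator | None = None) -> tuple[str, CatalyticTriad]:
    """Assemble a transposase from the shared synthetic ancestor scaffold.

    ``mutate_frac`` of the positions (triad, start methionine and GRPR box
    excluded) are substituted with random residues, emulating family
    divergence while keeping the proteins alignable.
    """
    pools = _ancestor_pools()
    layout = ancestor_layout(orf_aa, spacer2)
    prot = (pools["n_term"] + "D" + pools["linker"] + "D"
            + pools["spacer_pool"][:spacer2] + third_residue
            + pools["c_term_pool"][:layout["c_term"]])
    assert len(prot) == orf_aa
    triad = CatalyticTriad(d1_pos=layout["d1"], d2_pos=layout["d2"],
                           e3_pos=layout["e3"], third_residue=third_residue)
    if mutate_frac > 0:
        if rng is None:
            raise ValueError("mutation requires an rng")
        protected = {0, triad.d1_pos, triad.d2_pos, triad.e3_pos,
                     *range(_GRPR_AT, _GRPR_AT + 4)}
        seq = list(prot)
        n_mut = int(round(mutate_frac * orf_aa))
        candidates = [i for i in range(orf_aa) if i not in protected]
        for i in rng.choice(np.array(candidates), size=n_mut, replace=False):
            choices = _AA20.replace(seq[i], "")
            seq[i] = choices[rng.integers(len(choices))]
        prot = "".join(seq)
    return prot, triad


@lru_cache(maxsize=1)
def default_references() -> tuple[ReferenceTransposase, ...]:
    """The bundled synthetic reference panel (one per family architecture)."""
    specs = [
        ("Tc1_like_DD34E.synthetic", 34, "E", 101),
        ("mariner_like_DD34D.synthetic", 34, "D", 102),
        ("TRT_like_DD37E.synthetic", 37, "E", 103),
    ]
    refs = []
    for name, spacer2, third, seed in specs:
        rng = np.random.default_rng(seed)
        prot, triad = build_protein(spacer2=spacer2, third_residue=third,
                                    mutate_frac=0.12, rng=rng)
        refs.append(ReferenceTransposase(name=name, sequence=prot, triad=triad))
    return tuple(refs)
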