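"""Independent brute-force oracles the tests check the implementation against."""

from __future__ import annotations

import numpy as np

from sepexo.model_io import StructureModel


def brute_force_contacts(
    model: StructureModel, chain_pair: tuple[str, str], cutoff: float
) -> dict[tuple[int, int], float]:
    """O(N^2) all-heavy-atom-pairs contact map: (seq_a, seq_b) -> min distance."""
    out: dict[tuple[int, int], float] = {}
    chain_a = model.chain(chain_pair[0])
    chain_b = model.chain(chain_pair[1])
    for ra in chain_a.residues:
        xa = np.array([[a.x, a.y, a.z] for a in ra.heavy_atoms()])
        for rb in chain_b.residues:
            xb = np.array([[a.x, a.y, a.z] for a in rb.heavy_atoms()])
            d2 = ((xa[:, None, :] - xb[None, :, :]) ** 2).sum(axis=2)
            dmin2 = d2.min()
            if dmin2 <= cutoff * cutoff:
                out[(ra.seq_index, rb.seq_index)] = float(np.sqrt(dmin2))
    return out
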