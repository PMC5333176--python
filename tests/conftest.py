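import numpy as np
import pytest

from sseview.structure_io import (
    ProteinChain,
    Residue,
    SecondaryStructureElement,
    SSEKind,
)
from sseview.synthetic import ChainSpec, build_chain


@pytest.fixture
def standard_chain() -> ProteinChain:
    """Coil/helix/coil/sheet/coil/helix/coil chain with ideal geometry."""
    return build_chain(
        ChainSpec(
            blocks=[
                (SSEKind.COIL, 2),
                (SSEKind.HELIX, 10),
                (SSEKind.COIL, 3),
                (SSEKind.SHEET, 5),
                (SSEKind.COIL, 2),
                (SSEKind.HELIX, 6),
                (SSEKind.COIL, 2),
            ],
            source_id="ref",
        )
    )


def chain_from_kinds(kinds, ids, source_id="chain", x0=0.0):
    """Chain of 1-residue SSEs laid along +x (geometry mostly irrelevant)."""
    residues = [
        Residue(i, i + 1, "", "ALA", (x0 + 10.0 * i, 0.0, 0.0), chain="A")
        for i in range(len(kinds))
    ]
    sses = [
        SecondaryStructureElement(SSEKind(k), i, i, sid)
        for i, (k, sid) in enumerate(zip(kinds, ids))
    ]
    return ProteinChain(chain_id="A", source_id=source_id, residues=residues, sses=sses)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform-ish random proper rotation built from QR decomposition."""
    M = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(M)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q
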