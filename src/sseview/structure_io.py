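"""Structure parsing and the core domain model.

Chains are represented by their CA trace only.  Every chain carries a
complete secondary-structure tiling: each residue belongs to exactly one
:class:`SecondaryStructureElement`, with COIL filling the space between
annotated helix/sheet runs.

Parsers accept PDB text (ATOM / HELIX / SHEET / MODEL records) and classic
DSSP output.  A small self-describing JSON chain format is provided for
fixtures and for exchanging synthetic structures.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "SSEKind",
    "Residue",
    "SecondaryStructureElement",
    "ProteinChain",
    "Trajectory",
    "StructureError",
    "ValidationError",
    "parse_pdb",
    "parse_dssp",
    "sses_from_codes",
    "chain_to_json",
    "json_to_chain",
    "trajectory_to_json",
    "json_to_trajectory",
    "write_pdb",
]


class StructureError(ValueError):
    """Raised for malformed or empty structural input."""


class ValidationError(ValueError):
    """Raised when the JSON chain schema is violated; message carries the JSON path."""


class SSEKind(str, Enum):
    HELIX = "HELIX"
    SHEET = "SHEET"
    COIL = "COIL"

    @property
    def letter(self) -> str:
        return {"HELIX": "H", "SHEET": "E", "COIL": "C"}[self.value]


#: DSSP one-letter summary codes collapsed onto the three drawable kinds.
#: H/G/I (alpha, 3-10, pi) -> HELIX; E/B (strand, bridge) -> SHEET; rest -> COIL.
DSSP_CODE_MAP = {
    "H": SSEKind.HELIX,
    "G": SSEKind.HELIX,
    "I": SSEKind.HELIX,
    "E": SSEKind.SHEET,
    "B": SSEKind.SHEET,
}


@dataclass(frozen=True)
class Residue:
    """One amino acid, represented by its CA position.

    ``seq_index`` is the 0-based ordinal within the (possibly concatenated)
    chain; ``res_id``/``icode`` keep the author numbering for I/O and labels.
    """

    seq_index: int
    res_id: int
    icode: str
    name: str
    ca: tuple[float, float, float]
    chain: str = ""

    def ca_array(self) -> np.ndarray:
        return np.asarray(self.ca, dtype=float)


@dataclass(frozen=True)
class SecondaryStructureElement:
    kind: SSEKind
    start: int  # first residue seq_index, inclusive
    end: int  # last residue seq_index, inclusive
    sse_id: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"SSE {self.sse_id}: start {self.start} > end {self.end}")

    @property
    def residue_count(self) -> int:
        return self.end - self.start + 1


@dataclass
class ProteinChain:
    """Ordered CA trace plus its complete SSE tiling.

    ``segment_breaks`` holds the seq_index of every residue that starts a new
    polymer segment (multi-chain structures are concatenated into one track).
    """

    chain_id: str
    source_id: str
    residues: list[Residue]
    sses: list[SecondaryStructureElement]
    segment_breaks: set[int] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for i, res in enumerate(self.residues):
            if res.seq_index != i:
                raise StructureError(
                    f"residue seq_index {res.seq_index} at position {i}: must be dense and 0-based"
                )
            if not np.all(np.isfinite(res.ca_array())):
                raise StructureError(f"residue {res.res_id}{res.icode}: non-finite CA")
        cursor = 0
        for sse in self.sses:
            if sse.start != cursor:
                raise StructureError(
                    f"SSE tiling broken at seq_index {cursor} (next SSE starts at {sse.start})"
                )
            cursor = sse.end + 1
        if cursor != len(self.residues):
            raise StructureError(
                f"SSE tiling covers {cursor} residues, chain has {len(self.residues)}"
            )
        for b in self.segment_breaks:
            if not 0 <= b < len(self.residues):
                raise StructureError(f"segment break {b} outside residue range")

    # -- convenience accessors -------------------------------------------------

    def __len__(self) -> int:
        return len(self.residues)

    def ca_coords(self) -> np.ndarray:
        """(N, 3) array of CA coordinates in file order."""
        return np.array([r.ca for r in self.residues], dtype=float)

    def sse_by_id(self, sse_id: str) -> SecondaryStructureElement:
        for sse in self.sses:
            if sse.sse_id == sse_id:
                return sse
        raise KeyError(sse_id)

    def elements(self, kinds: Iterable[SSEKind] = (SSEKind.HELIX, SSEKind.SHEET)):
        """The alignable (non-coil, by default) SSEs in chain order."""
        kinds = set(kinds)
        return [s for s in self.sses if s.kind in kinds]

    def sse_coords(self, sse: SecondaryStructureElement) -> np.ndarray:
        return self.ca_coords()[sse.start : sse.end + 1]

    def with_coords(self, coords: np.ndarray) -> "ProteinChain":
        """Copy of the chain with CA coordinates replaced (same ordering)."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.residues), 3):
            raise ValueError(f"expected {(len(self.residues), 3)} coords, got {coords.shape}")
        residues = [
            replace(r, ca=(float(x), float(y), float(z)))
            for r, (x, y, z) in zip(self.residues, coords)
        ]
        return ProteinChain(
            chain_id=self.chain_id,
            source_id=self.source_id,
            residues=residues,
            sses=list(self.sses),
            segment_breaks=set(self.segment_breaks),
        )

    def with_sses(self, sses: Sequence[SecondaryStructureElement]) -> "ProteinChain":
        return ProteinChain(
            chain_id=self.chain_id,
            source_id=self.source_id,
            residues=list(self.residues),
            sses=list(sses),
            segment_breaks=set(self.segment_breaks),
        )


@dataclass
class Trajectory:
    """Ordered MD frames of one protein; all frames share residue numbering."""

    frames: list[ProteinChain]
    frame_labels: list[str]

    def __post_init__(self) -> None:
        if len(self.frames) != len(self.frame_labels):
            raise ValueError("one label per frame required")
        if not self.frames:
            raise ValueError("empty trajectory")
        ref = self.frames[0]
        for k, fr in enumerate(self.frames[1:], start=1):
            if len(fr) != len(ref):
                raise StructureError(f"frame {k}: residue count differs from frame 0")
            for a, b in zip(ref.residues, fr.residues):
                if (a.res_id, a.icode) != (b.res_id, b.icode):
                    raise StructureError(
                        f"frame {k}: residue numbering mismatch at seq_index {a.seq_index}"
                    )

    def __len__(self) -> int:
        return len(self.frames)


# ---------------------------------------------------------------------------
# tiling helpers
# ---------------------------------------------------------------------------


def _label_sses(runs: list[tuple[SSEKind, int, int]], prefix: str = "") -> list[SecondaryStructureElement]:
    return [
        SecondaryStructureElement(kind, start, end, f"{prefix}{kind.letter}{i}")
        for i, (kind, start, end) in enumerate(runs)
    ]


def tile_from_kinds(kinds: Sequence[SSEKind], prefix: str = "") -> list[SecondaryStructureElement]:
    """Run-length encode a per-residue kind sequence into a complete SSE tiling."""
    runs: list[tuple[SSEKind, int, int]] = []
    for i, k in enumerate(kinds):
        if runs and runs[-1][0] == k and runs[-1][2] == i - 1:
            runs[-1] = (k, runs[-1][1], i)
        else:
            runs.append((k, i, i))
    return _label_sses(runs, prefix)


def sses_from_codes(codes: str, prefix: str = "") -> list[SecondaryStructureElement]:
    """Tiling from per-residue DSSP one-letter codes (blank/other -> coil)."""
    kinds = [DSSP_CODE_MAP.get(c.upper(), SSEKind.COIL) for c in codes]
    return tile_from_kinds(kinds, prefix)


# ---------------------------------------------------------------------------
# PDB
# ---------------------------------------------------------------------------


def parse_pdb(text: str, chain_filter: set[str] | None = None) -> list[ProteinChain]:
    """Parse PDB text into one :class:`ProteinChain` per MODEL.

    Residues are built from CA atoms in file order (first alternate location
    wins).  HELIX/SHEET records provide the helix/sheet runs; everything else
    becomes coil.  When several chains are selected they are concatenated,
    with a segment break recorded at each junction.
    """
    lines = text.splitlines()
    helices: list[tuple[str, int, str, str, int, str]] = []
    sheets: list[tuple[str, int, str, str, int, str]] = []
    models: list[list[str]] = []
    current: list[str] = []
    in_model = False
    for ln in lines:
        rec = ln[:6]
        if rec == "HELIX ":
            helices.append(
                (
                    ln[19],
                    int(ln[21:25]),
                    ln[25].strip(),
                    ln[31],
                    int(ln[33:37]),
                    ln[37].strip() if len(ln) > 37 else "",
                )
            )
        elif rec == "SHEET ":
            sheets.append(
                (
                    ln[21],
                    int(ln[22:26]),
                    ln[26].strip(),
                    ln[32],
                    int(ln[33:37]),
                    ln[37].strip() if len(ln) > 37 else "",
                )
            )
        elif rec == "MODEL ":
            in_model = True
            current = []
        elif rec == "ENDMDL":
            models.append(current)
            in_model = False
            current = []
        elif rec in ("ATOM  ", "TER   "):
            current.append(ln)
    if not in_model and current:
        if models:
            # trailing ATOM records outside any MODEL are ignored
            pass
        else:
            models.append(current)
    if not models:
        models.append([])

    chains = [
        _build_model(atoms, helices, sheets, chain_filter, model_index=i, n_models=len(models))
        for i, atoms in enumerate(models)
    ]
    return chains


def _build_model(
    atom_lines: list[str],
    helices,
    sheets,
    chain_filter: set[str] | None,
    model_index: int,
    n_models: int,
) -> ProteinChain:
    residues: list[Residue] = []
    index_of: dict[tuple[str, int, str], int] = {}
    seen: set[tuple[str, int, str]] = set()
    chain_order: list[str] = []
    breaks: set[int] = set()
    last_chain: str | None = None
    for ln in atom_lines:
        if ln[:6] != "ATOM  ":
            continue
        if ln[12:16].strip() != "CA":
            continue
        cid = ln[21]
        if chain_filter is not None and cid not in chain_filter:
            continue
        key = (cid, int(ln[22:26]), ln[26].strip())
        if key in seen:  # alternate location: first wins
            continue
        seen.add(key)
        ca = (float(ln[30:38]), float(ln[38:46]), float(ln[46:54]))
        if last_chain is not None and cid != last_chain:
            breaks.add(len(residues))
        if cid not in chain_order:
            chain_order.append(cid)
        last_chain = cid
        index_of[key] = len(residues)
        residues.append(
            Residue(
                seq_index=len(residues),
                res_id=key[1],
                icode=key[2],
                name=ln[17:20].strip(),
                ca=ca,
                chain=cid,
            )
        )
    if not residues:
        raise StructureError("empty structure: no CA atoms found")

    kinds = [SSEKind.COIL] * len(residues)

    def apply(records, kind: SSEKind) -> None:
        for c1, s1, i1, c2, s2, i2 in records:
            if chain_filter is not None and c1 not in chain_filter:
                continue
            a = index_of.get((c1, s1, i1))
            b = index_of.get((c2, s2, i2))
            if a is None or b is None:
                # clip to the residues that are present
                cands = [
                    idx
                    for (cc, rr, _ic), idx in index_of.items()
                    if cc == c1 and s1 <= rr <= s2
                ]
                if not cands:
                    warnings.warn(
                        f"{kind.value} record {c1}{s1}-{s2} references residues absent "
                        "from ATOM records; dropped"
                    )
                    continue
                warnings.warn(
                    f"{kind.value} record {c1}{s1}-{s2} clipped to available residues"
                )
                a, b = min(cands), max(cands)
            for idx in range(min(a, b), max(a, b) + 1):
                if kinds[idx] is SSEKind.COIL:
                    kinds[idx] = kind

    apply(helices, SSEKind.HELIX)
    apply(sheets, SSEKind.SHEET)

    source = "model" + str(model_index + 1) if n_models > 1 else "pdb"
    return ProteinChain(
        chain_id="+".join(chain_order),
        source_id=source,
        residues=residues,
        sses=tile_from_kinds(kinds),
        segment_breaks=breaks,
    )


# PDB writing (used by the `synth` CLI to emit text fixtures) ---------------


def _place(line: list[str], start: int, text: str) -> None:
    for k, ch in enumerate(text):
        line[start + k] = ch


def _record(fields: list[tuple[int, str]]) -> str:
    line = [" "] * 80
    for start, text in fields:
        _place(line, start, text)
    return "".join(line).rstrip()


def write_pdb(chains: ProteinChain | Sequence[ProteinChain]) -> str:
    """Serialize one chain (or trajectory frames as MODELs) to PDB text.

    Only CA atoms plus HELIX/SHEET annotation records are written — enough
    to round-trip through :func:`parse_pdb`.
    """
    if isinstance(chains, ProteinChain):
        frames: Sequence[ProteinChain] = [chains]
        multi = False
    else:
        frames = chains
        multi = len(frames) > 1
    first = frames[0]
    out: list[str] = []
    h_ser = s_ser = 0
    for sse in first.sses:
        r1, r2 = first.residues[sse.start], first.residues[sse.end]
        if sse.kind is SSEKind.HELIX:
            h_ser += 1
            out.append(
                _record(
                    [
                        (0, "HELIX"),
                        (7, f"{h_ser:>3}"),
                        (11, f"{h_ser:>3}"),
                        (15, f"{r1.name:>3}"),
                        (19, (r1.chain or "A")[0]),
                        (21, f"{r1.res_id:>4}"),
                        (25, r1.icode or " "),
                        (27, f"{r2.name:>3}"),
                        (31, (r2.chain or "A")[0]),
                        (33, f"{r2.res_id:>4}"),
                        (37, r2.icode or " "),
                        (38, " 1"),
                    ]
                )
            )
        elif sse.kind is SSEKind.SHEET:
            s_ser += 1
            out.append(
                _record(
                    [
                        (0, "SHEET"),
                        (7, f"{s_ser:>3}"),
                        (11, f"{'S':>3}"),
                        (14, " 1"),
                        (17, f"{r1.name:>3}"),
                        (21, (r1.chain or "A")[0]),
                        (22, f"{r1.res_id:>4}"),
                        (26, r1.icode or " "),
                        (28, f"{r2.name:>3}"),
                        (32, (r2.chain or "A")[0]),
                        (33, f"{r2.res_id:>4}"),
                        (37, r2.icode or " "),
                        (38, " 0"),
                    ]
                )
            )
    for m, chain in enumerate(frames):
        if multi:
            out.append(f"MODEL     {m + 1:>4}")
        for i, res in enumerate(chain.residues):
            x, y, z = res.ca
            out.append(
                _record(
                    [
                        (0, "ATOM"),
                        (6, f"{i + 1:>5}"),
                        (12, " CA "),
                        (17, f"{res.name:>3}"),
                        (21, (res.chain or "A")[0]),
                        (22, f"{res.res_id:>4}"),
                        (26, res.icode or " "),
                        (30, f"{x:8.3f}"),
                        (38, f"{y:8.3f}"),
                        (46, f"{z:8.3f}"),
                        (54, "  1.00  0.00"),
                        (77, "C"),
                    ]
                )
            )
        if multi:
            out.append("ENDMDL")
    out.append("END")
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# DSSP
# ---------------------------------------------------------------------------


def parse_dssp(text: str, chain: ProteinChain) -> list[SecondaryStructureElement]:
    """Map classic DSSP output onto ``chain`` and return the SSE tiling.

    DSSP summary codes collapse as H/G/I -> helix, E/B -> sheet, rest ->
    coil (the conventional 3-state reduction; configurable only in code).
    """
    codes: dict[tuple[str, int, str], str] = {}
    in_table = False
    for ln in text.splitlines():
        if not in_table:
            if ln.lstrip().startswith("#  RESIDUE"):
                in_table = True
            continue
        if len(ln) < 17:
            continue
        if ln[13] == "!":  # chain-break pseudo residue
            continue
        try:
            resnum = int(ln[5:10])
        except ValueError:
            continue
        codes[(ln[11].strip(), resnum, ln[10].strip())] = ln[16]
    if not codes:
        raise StructureError("no residue table found in DSSP input")

    dssp_chains = {c for c, _, _ in codes}
    sole_chain = next(iter(dssp_chains)) if len(dssp_chains) == 1 else None
    kinds: list[SSEKind] = []
    for res in chain.residues:
        key = (res.chain, res.res_id, res.icode)
        if key not in codes and ("", res.res_id, res.icode) in codes:
            key = ("", res.res_id, res.icode)
        if key not in codes and sole_chain is not None:
            key = (sole_chain, res.res_id, res.icode)
        if key not in codes:
            raise StructureError(
                f"DSSP output does not resolve residue {res.chain}{res.res_id}{res.icode}"
            )
        kinds.append(DSSP_CODE_MAP.get(codes[key].upper(), SSEKind.COIL))
    return tile_from_kinds(kinds)


# ---------------------------------------------------------------------------
# JSON chain format
# ---------------------------------------------------------------------------


def chain_to_json(chain: ProteinChain, indent: int | None = None) -> str:
    doc = {
        "source_id": chain.source_id,
        "chain_id": chain.chain_id,
        "residues": [
            {
                "res_id": r.res_id,
                "icode": r.icode,
                "name": r.name,
                "chain": r.chain,
                "ca": [r.ca[0], r.ca[1], r.ca[2]],
            }
            for r in chain.residues
        ],
        "sses": [
            {"kind": s.kind.value, "start": s.start, "end": s.end, "id": s.sse_id}
            for s in chain.sses
        ],
        "segment_breaks": sorted(chain.segment_breaks),
    }
    return json.dumps(doc, indent=indent, sort_keys=True)


def _expect(doc: dict, key: str, path: str):
    if key not in doc:
        raise ValidationError(f"{path}: missing required key '{key}'")
    return doc[key]


def json_to_chain(text: str) -> ProteinChain:
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ValidationError(f"$: not valid JSON ({exc})") from exc
    if not isinstance(doc, dict):
        raise ValidationError("$: expected a JSON object")
    residues = []
    for i, rd in enumerate(_expect(doc, "residues", "$")):
        path = f"$.residues[{i}]"
        ca = _expect(rd, "ca", path)
        if not (isinstance(ca, list) and len(ca) == 3):
            raise ValidationError(f"{path}.ca: expected [x, y, z]")
        residues.append(
            Residue(
                seq_index=i,
                res_id=int(_expect(rd, "res_id", path)),
                icode=str(rd.get("icode", "")),
                name=str(rd.get("name", "ALA")),
                ca=(float(ca[0]), float(ca[1]), float(ca[2])),
                chain=str(rd.get("chain", "")),
            )
        )
    sses = []
    for i, sd in enumerate(_expect(doc, "sses", "$")):
        path = f"$.sses[{i}]"
        kind = _expect(sd, "kind", path)
        try:
            kind = SSEKind(kind)
        except ValueError as exc:
            raise ValidationError(f"{path}.kind: unknown kind {kind!r}") from exc
        sses.append(
            SecondaryStructureElement(
                kind=kind,
                start=int(_expect(sd, "start", path)),
                end=int(_expect(sd, "end", path)),
                sse_id=str(sd.get("id", f"{kind.letter}{i}")),
            )
        )
    try:
        return ProteinChain(
            chain_id=str(_expect(doc, "chain_id", "$")),
            source_id=str(_expect(doc, "source_id", "$")),
            residues=residues,
            sses=sses,
            segment_breaks={int(b) for b in doc.get("segment_breaks", [])},
        )
    except StructureError as exc:
        raise ValidationError(f"$.sses: {exc}") from exc


def trajectory_to_json(traj: Trajectory, indent: int | None = None) -> str:
    doc = {
        "frames": [json.loads(chain_to_json(f)) for f in traj.frames],
        "frame_labels": list(traj.frame_labels),
    }
    return json.dumps(doc, indent=indent, sort_keys=True)


def json_to_trajectory(text: str) -> Trajectory:
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ValidationError(f"$: not valid JSON ({exc})") from exc
    frames = [json_to_chain(json.dumps(f)) for f in _expect(doc, "frames", "$")]
    labels = doc.get("frame_labels") or [f"frame{i}" for i in range(len(frames))]
    return Trajectory(frames=frames, frame_labels=[str(x) for x in labels])
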