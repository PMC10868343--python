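"""Loop-motif data structures, the library JSON format, and curation.

A motif describes a recurrent hairpin or internal loop: how many
unpaired nucleotides sit on each strand, the closing pair(s) delimiting
the loop, annotated within-loop interactions (non-canonical pairs,
stacks), and an alignment of observed instance sequences.  Model
positions are numbered 0-based along strand 1 then strand 2, with the
closing-pair nucleotides included (they carry sequence information used
by the scorer).

Curation mirrors the preparation of a reliable motif set for
statistical scanning: motifs with too few unique instances are dropped,
motifs with no unpaired base are dropped (nothing to search for), and
motifs whose instances mix loops of different sizes are split into one
motif per strand-length vector.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import List, Optional, Tuple

LOOP_TYPES = ("hairpin", "internal")
_ALPHA = set("ACGU")


class MotifFormatError(ValueError):
    pass


class MotifValidationError(ValueError):
    pass


def normalize_instance(s: str) -> str:
    return s.upper().replace("T", "U")


def canonical_closing_pairs(loop_type: str, strand_lengths) -> List[Tuple[int, int]]:
    if loop_type == "hairpin":
        (l1,) = strand_lengths
        return [(0, l1 + 1)]
    l1, l2 = strand_lengths
    # outer pair then inner pair
    return [(0, l1 + l2 + 3), (l1 + 1, l1 + 2)]


@dataclass
class LoopMotif:
    motif_id: str
    loop_type: str
    strand_lengths: List[int]
    closing_pairs: List[Tuple[int, int]]
    interactions: List[Tuple[int, int, str]] = field(default_factory=list)
    instances: List[str] = field(default_factory=list)

    @property
    def n_positions(self) -> int:
        return sum(self.strand_lengths) + 2 * len(self.closing_pairs)

    @property
    def n_loop_positions(self) -> int:
        return sum(self.strand_lengths)

    @property
    def strand_position_lengths(self) -> List[int]:
        """Model positions per strand, closing nucleotides included."""
        if self.loop_type == "hairpin":
            return [self.strand_lengths[0] + 2]
        return [self.strand_lengths[0] + 2, self.strand_lengths[1] + 2]

    def unique_instances(self) -> List[str]:
        seen, out = set(), []
        for inst in self.instances:
            u = normalize_instance(inst)
            if u not in seen:
                seen.add(u)
                out.append(u)
        return out

    def validate(self, strict_lengths: bool = True) -> None:
        m = self.motif_id
        if self.loop_type not in LOOP_TYPES:
            raise MotifValidationError(f"{m}: unknown loop_type {self.loop_type!r}")
        n_strands = 1 if self.loop_type == "hairpin" else 2
        if len(self.strand_lengths) != n_strands:
            raise MotifValidationError(
                f"{m}: {self.loop_type} motif needs {n_strands} strand length(s)")
        if any((not isinstance(x, int)) or x < 0 for x in self.strand_lengths):
            raise MotifValidationError(f"{m}: strand_lengths must be non-negative ints")
        n_pairs = 1 if self.loop_type == "hairpin" else 2
        if len(self.closing_pairs) != n_pairs:
            raise MotifValidationError(
                f"{m}: {self.loop_type} motif needs {n_pairs} closing pair(s)")
        npos = self.n_positions
        for i, j in self.closing_pairs:
            if not (0 <= i < npos and 0 <= j < npos and i != j):
                raise MotifValidationError(f"{m}: closing pair {(i, j)} out of range")
        for i, j, _lab in self.interactions:
            if not (0 <= i < npos and 0 <= j < npos):
                raise MotifValidationError(f"{m}: interaction {(i, j)} out of range")
        widths = self.strand_position_lengths
        for inst in self.instances:
            u = normalize_instance(inst)
            parts = u.split("&")
            if len(parts) != n_strands:
                raise MotifValidationError(
                    f"{m}: instance {inst!r} has {len(parts)} strands, expected {n_strands}")
            if any(set(p) - _ALPHA for p in parts):
                raise MotifValidationError(f"{m}: instance {inst!r} has non-ACGU characters")
            if strict_lengths and [len(p) for p in parts] != widths:
                raise MotifValidationError(
                    f"{m}: instance {inst!r} lengths {[len(p) for p in parts]} "
                    f"do not match strand widths {widths}")

    def instance_model_sequence(self, inst: str) -> str:
        """Instance string in model coordinates (strands concatenated)."""
        return normalize_instance(inst).replace("&", "")


@dataclass
class MotifLibrary:
    motifs: List[LoopMotif]
    source: str = ""
    curation_log: List[Tuple[str, str, str]] = field(default_factory=list)

    def validate(self) -> None:
        ids = [m.motif_id for m in self.motifs]
        if len(ids) != len(set(ids)):
            raise MotifValidationError("duplicate motif ids in library")
        for m in self.motifs:
            m.validate()

    def get(self, motif_id: str) -> LoopMotif:
        for m in self.motifs:
            if m.motif_id == motif_id:
                return m
        raise KeyError(motif_id)


def read_motif_library(path) -> MotifLibrary:
    try:
        with open(path) as fh:
            raw = json.load(fh)
    except json.JSONDecodeError as e:
        raise MotifFormatError(f"malformed motif library JSON: {e}") from e
    motifs = []
    for entry in raw.get("motifs", []):
        mid = entry.get("id", "<missing id>")
        try:
            motif = LoopMotif(
                motif_id=mid,
                loop_type=entry["type"],
                strand_lengths=list(entry["strand_lengths"]),
                closing_pairs=[tuple(p) for p in entry["closing_pairs"]],
                interactions=[(int(i), int(j), str(lab))
                              for i, j, lab in entry.get("interactions", [])],
                instances=[normalize_instance(s) for s in entry.get("instances", [])],
            )
        except (KeyError, TypeError, ValueError) as e:
            raise MotifFormatError(f"motif {mid}: malformed entry ({e})") from e
        motifs.append(motif)
    lib = MotifLibrary(motifs=motifs, source=raw.get("source", ""),
                       curation_log=[tuple(x) for x in raw.get("curation_log", [])])
    lib.validate()
    return lib


def write_motif_library(lib: MotifLibrary, path) -> None:
    doc = {
        "source": lib.source,
        "curation_log": [list(x) for x in lib.curation_log],
        "motifs": [
            {
                "id": m.motif_id,
                "type": m.loop_type,
                "strand_lengths": list(m.strand_lengths),
                "closing_pairs": [list(p) for p in m.closing_pairs],
                "interactions": [[i, j, lab] for i, j, lab in m.interactions],
                "instances": list(m.instances),
            }
            for m in lib.motifs
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")


def _instance_strand_lengths(motif: LoopMotif, inst: str) -> Tuple[int, ...]:
    parts = normalize_instance(inst).split("&")
    return tuple(len(p) - 2 for p in parts)


def curate_library(lib: MotifLibrary, min_unique_occurrences: int = 5) -> MotifLibrary:
    """Apply the reliability filters; every action is logged.

    Returns a new library; curation is idempotent and an empty result is
    legal.
    """
    log = list(lib.curation_log)
    out: List[LoopMotif] = []

    def admit(m: LoopMotif) -> None:
        n_unique = len(m.unique_instances())
        if n_unique < min_unique_occurrences:
            log.append((m.motif_id, "removed",
                        f"insufficient unique occurrences ({n_unique} < "
                        f"{min_unique_occurrences})"))
            return
        if m.n_loop_positions == 0:
            log.append((m.motif_id, "removed", "no unpaired base"))
            return
        out.append(m)

    for m in lib.motifs:
        vectors = []
        for inst in m.instances:
            v = _instance_strand_lengths(m, inst)
            if v not in vectors:
                vectors.append(v)
        if len(vectors) <= 1:
            admit(m)
            continue
        log.append((m.motif_id, "split",
                    f"instances span {len(vectors)} distinct loop sizes"))
        for k, v in enumerate(vectors, start=1):
            insts = [i for i in m.instances if _instance_strand_lengths(m, i) == v]
            npos = sum(v) + 2 * (1 if m.loop_type == "hairpin" else 2)
            child = replace(
                m,
                motif_id=f"{m.motif_id}.s{k}",
                strand_lengths=list(v),
                closing_pairs=canonical_closing_pairs(m.loop_type, v),
                interactions=[(i, j, lab) for i, j, lab in m.interactions
                              if i < npos and j < npos],
                instances=insts,
            )
            admit(child)
    return MotifLibrary(motifs=out, source=lib.source, curation_log=log)
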