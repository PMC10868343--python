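"""Seeded synthetic positive/background datasets with planted loop motifs.

Emulates an in-vitro-selection contrast: short random RNAs in which a
structured loop motif — a loop sequence variant supported by a designed
Watson-Crick stem — is planted at a higher frequency in the positive set
than in the background set.  Ground truth (which record carries which
variant, where) is returned alongside the sequences so recovery can be
scored exactly.

The default motif is a hairpin with a 4-nt loop whose instances centre
on GCAC/GCAA-type loop sequences, the classic stem-loop binder
configuration; decoy motifs with unrelated consensus are provided for
specificity checks.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

from .fold import _CAN_PAIR, _IDX
from .motif_library import LoopMotif

_WC = {"A": "U", "U": "A", "C": "G", "G": "C"}


class SynthError(ValueError):
    pass


def revcomp(s: str) -> str:
    return "".join(_WC[c] for c in reversed(s))


def default_motif() -> LoopMotif:
    """Planted hairpin motif: 4-nt loop, GCAx consensus, varied closing pairs."""
    return LoopMotif(
        motif_id="HL_SYNTH.1", loop_type="hairpin", strand_lengths=[4],
        closing_pairs=[(0, 5)], interactions=[(1, 4, "tWH")],
        instances=["CGCACG", "CGCAAG", "GGCACC", "UGCACA",
                   "AGCACU", "CGCAUG", "GGCAAC", "UGCAAA"])


def decoy_motifs() -> List[LoopMotif]:
    """Motifs never planted, spanning the loop geometries the scanner
    searches: same-size and off-size hairpins with unrelated consensus,
    plus an internal-loop decoy.  A panel of six keeps the false-flag
    rate estimate in recovery studies from being dominated by single
    binomial events."""
    return [
        LoopMotif("HL_DECOY.1", "hairpin", [4], [(0, 5)], [],
                  ["CAUUAG", "GAUUAC", "CAUUCG", "UAUUAA",
                   "GAUUGC", "AAUUCU", "CAUUGG"]),
        LoopMotif("HL_DECOY.2", "hairpin", [5], [(0, 6)], [],
                  ["CUUCGGG", "GUUCGGC", "CUUCGAG", "AUUCGGU",
                   "GUUCGUC", "CUUCGCG"]),
        LoopMotif("HL_DECOY.3", "hairpin", [3], [(0, 4)], [],
                  ["CGAAG", "GGAAC", "UGAAA", "AGAAU", "CGACG", "GGAUC"]),
        LoopMotif("HL_DECOY.4", "hairpin", [6], [(0, 7)], [],
                  ["CAACUACG", "GAACUAUC", "CAACUGCG", "UAACUACA",
                   "GAACCACC", "CAAUUACG"]),
        LoopMotif("HL_DECOY.5", "hairpin", [4], [(0, 5)], [],
                  ["GCUUGC", "CCUUGG", "ACUUGU", "GCUUAC", "UCUUGA"]),
        LoopMotif("IL_DECOY.1", "internal", [2, 2], [(0, 7), (3, 4)], [],
                  ["CAAG&CACG", "GAAC&GACC", "CAAG&CAAG",
                   "UAAA&UACA", "CACG&CAAG"]),
    ]


@dataclass
class SynthConfig:
    n_pos: int = 200
    n_bg: int = 200
    seq_length: int = 60
    motif: LoopMotif = field(default_factory=default_motif)
    variant_weights: Dict[str, float] = field(
        default_factory=lambda: {"CGCACG": 0.75, "CGCAAG": 0.25})
    f_pos: float = 0.3
    f_bg: float = 0.05
    stem_length: int = 6
    gc_bias: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if abs(sum(self.variant_weights.values()) - 1.0) > 1e-9:
            raise SynthError("variant_weights must sum to 1")
        if not (0 <= self.f_pos <= 1 and 0 <= self.f_bg <= 1):
            raise SynthError("planting probabilities must lie in [0, 1]")
        if self.stem_length < 1:
            raise SynthError("stem_length must be >= 1")
        if not (0 < self.gc_bias < 1):
            raise SynthError("gc_bias must lie in (0, 1)")
        foot = self.motif.n_positions + 2 * self.stem_length + 4
        if self.seq_length < foot:
            raise SynthError(
                f"seq_length {self.seq_length} below motif footprint {foot}")


def _random_seq(n: int, gc: float, rng: random.Random) -> str:
    w = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choices("ACGU", weights=w, k=n))


def _pairable(a: str, b: str) -> bool:
    return bool(_CAN_PAIR[_IDX[a], _IDX[b]])


def plant_instance(background_seq: str, motif: LoopMotif, variant: str,
                   stem_length: int, rng: random.Random):
    """Embed a stem-supported instance of ``variant`` into the sequence.

    Returns (sequence, strand_spans, closing_pair_coords) with 0-based
    half-open loop spans, matching hit coordinates.
    """
    parts = variant.replace("T", "U").upper().split("&")
    widths = motif.strand_position_lengths
    if [len(p) for p in parts] != widths:
        raise SynthError(f"variant {variant!r} does not fit motif strand widths {widths}")
    for p in parts:
        if not _pairable(p[0], p[-1]) and motif.loop_type == "hairpin":
            raise SynthError(f"variant {variant!r} closing nucleotides cannot pair")
    stem = _random_seq(stem_length, 0.75, rng)  # GC-rich stems plant more firmly
    if motif.loop_type == "hairpin":
        insert = stem + parts[0] + revcomp(stem)
        a_off = stem_length          # closing 5' within insert
        b_off = stem_length + len(parts[0]) - 1
        closings = [(a_off, b_off)]
        spans = [(a_off + 1, b_off)]
    else:
        s1, s2 = parts
        if not (_pairable(s1[0], s2[-1]) and _pairable(s1[-1], s2[0])):
            raise SynthError(f"variant {variant!r} closing nucleotides cannot pair")
        inner_stem = _random_seq(stem_length, 0.75, rng)
        cap = "UUCG"
        insert = (stem + s1 + inner_stem + cap + revcomp(inner_stem)
                  + s2 + revcomp(stem))
        a = stem_length                               # outer 5'
        c = stem_length + len(s1) - 1                 # inner 5'
        d = stem_length + len(s1) + 2 * stem_length + 4   # inner 3'
        b = d + len(s2) - 1                           # outer 3'
        closings = [(a, b), (c, d)]
        spans = [(a + 1, c), (d + 1, b)]
    if len(insert) > len(background_seq):
        raise SynthError("sequence too short for the planted insert")
    off = rng.randrange(0, len(background_seq) - len(insert) + 1)
    seq = background_seq[:off] + insert + background_seq[off + len(insert):]
    spans = [(x + off, y + off) for x, y in spans]
    closings = [(x + off, y + off) for x, y in closings]
    return seq, spans, closings


@dataclass
class TruthRow:
    record_id: str
    motif_id: str
    variant: str
    strand_spans: List[Tuple[int, int]]
    closing_pair_coords: List[Tuple[int, int]]


def generate_datasets(cfg: SynthConfig):
    """Returns (positive records, background records, truth rows); records
    are (id, sequence) tuples, fully determined by ``cfg.seed``."""
    cfg.validate()
    rng = random.Random(cfg.seed)
    variants = sorted(cfg.variant_weights)
    weights = [cfg.variant_weights[v] for v in variants]
    truth: List[TruthRow] = []

    def make_set(prefix: str, n: int, f_plant: float):
        records = []
        for i in range(n):
            rid = f"{prefix}_{i:04d}"
            seq = _random_seq(cfg.seq_length, cfg.gc_bias, rng)
            if rng.random() < f_plant:
                variant = rng.choices(variants, weights=weights)[0]
                seq, spans, closings = plant_instance(
                    seq, cfg.motif, variant, cfg.stem_length, rng)
                truth.append(TruthRow(rid, cfg.motif.motif_id, variant,
                                      spans, closings))
            records.append((rid, seq))
        return records

    pos = make_set("pos", cfg.n_pos, cfg.f_pos)
    bg = make_set("bg", cfg.n_bg, cfg.f_bg)
    return pos, bg, truth


def write_fasta(records, path) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n{seq}\n")


def write_truth(truth: List[TruthRow], path) -> None:
    """TSV with 1-based inclusive coordinates of the first loop strand."""
    with open(path, "w") as fh:
        fh.write("record_id\tmotif_id\tvariant\tstart\tend\n")
        for row in truth:
            a, b = row.strand_spans[0]
            fh.write(f"{row.record_id}\t{row.motif_id}\t{row.variant}\t{a + 1}\t{b}\n")
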