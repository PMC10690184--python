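"""IR1 (FXRE) motif scanning.

The FXR/RXR heterodimer binds an inverted repeat-1 element: two
nuclear-receptor hexamer half-sites in head-to-head orientation
separated by exactly one spacer base.  The default half-site consensus
is RGGTCA (IUPAC R = A/G), so a perfect IR1 13-mer reads

    RGGTCA . N . TGACCY

with the right half the reverse complement of the left.  Matching is
IUPAC-aware with a configurable mismatch budget per half site; an
optional position weight matrix supplies log-odds scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

IUPAC = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"},
    "B": {"C", "G", "T"}, "D": {"A", "G", "T"},
    "H": {"A", "C", "T"}, "V": {"A", "C", "G"},
    "N": {"A", "C", "G", "T"},
}

IUPAC_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

HALF_SITE_LEN = 6
SPACER_LEN = 1
IR1_LEN = 2 * HALF_SITE_LEN + SPACER_LEN  # 13


def reverse_complement(seq: str) -> str:
    """Reverse complement over the DNA alphabet ACGTN (case kept)."""
    bad = set(seq.upper()) - set("ACGTN")
    if bad:
        raise ValueError(f"non-DNA characters in sequence: {sorted(bad)}")
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class HalfSiteModel:
    """A 6-bp nuclear-receptor half site, consensus plus optional PWM.

    The PWM, when given, is 6x4 (columns A, C, G, T) with each row
    summing to 1; log-odds use a uniform 0.25 background with a 0.01
    pseudocount.
    """

    consensus: str = "RGGTCA"
    pwm: np.ndarray | None = None
    pseudocount: float = 0.01

    def __post_init__(self):
        self.consensus = self.consensus.upper()
        if len(self.consensus) != HALF_SITE_LEN:
            raise ValueError("half-site consensus must be 6 letters")
        if any(c not in IUPAC for c in self.consensus):
            raise ValueError(f"non-IUPAC letter in {self.consensus!r}")
        if self.pwm is not None:
            self.pwm = np.asarray(self.pwm, dtype=float)
            if self.pwm.shape != (HALF_SITE_LEN, 4):
                raise ValueError("PWM must be 6x4 (A,C,G,T)")
            if not np.allclose(self.pwm.sum(axis=1), 1.0):
                raise ValueError("PWM rows must sum to 1")

    @property
    def rc_consensus(self) -> str:
        return self.consensus.translate(IUPAC_COMPLEMENT)[::-1]

    def mismatches(self, half: str, reverse: bool = False) -> int:
        """Count of positions where ``half`` violates the (rc-)consensus."""
        pattern = self.rc_consensus if reverse else self.consensus
        return sum(
            base not in IUPAC[code]
            for base, code in zip(half.upper(), pattern)
        )

    def log_odds(self, half: str, reverse: bool = False) -> float:
        if self.pwm is None:
            raise ValueError("model has no PWM")
        pwm = self.pwm[::-1, ::-1] if reverse else self.pwm
        idx = {"A": 0, "C": 1, "G": 2, "T": 3}
        score = 0.0
        for i, base in enumerate(half.upper()):
            p = pwm[i, idx[base]] if base in idx else 0.25
            score += np.log2((p + self.pseudocount) / (0.25 + self.pseudocount))
        return float(score)


@dataclass(frozen=True)
class IR1Hit:
    position: int  # 0-based offset of the 13-mer start
    sequence: str
    mismatches_left: int
    mismatches_right: int
    score: float
    strand: str = "+"

    @property
    def total_mismatches(self) -> int:
        return self.mismatches_left + self.mismatches_right


def scan_ir1(
    seq: str,
    model: HalfSiteModel | None = None,
    max_mismatch_per_half: int = 1,
) -> list[IR1Hit]:
    """Find IR1 occurrences in ``seq``.

    A hit at offset i requires seq[i:i+6] to match the half-site
    consensus and seq[i+7:i+13] its reverse complement, each within the
    mismatch budget; the spacer base (i+6) is free.  A perfect IR1 is
    its own reverse complement, so each position is reported once, on
    the + strand.  Sequences shorter than 13 yield no hits.  Score is
    -(total mismatches), or PWM log-odds summed over both halves when
    the model carries a PWM.
    """
    model = model or HalfSiteModel()
    seq_u = seq.upper()
    hits = []
    for i in range(len(seq_u) - IR1_LEN + 1):
        left = seq_u[i : i + HALF_SITE_LEN]
        right = seq_u[i + HALF_SITE_LEN + SPACER_LEN : i + IR1_LEN]
        ml = model.mismatches(left)
        if ml > max_mismatch_per_half:
            continue
        mr = model.mismatches(right, reverse=True)
        if mr > max_mismatch_per_half:
            continue
        if model.pwm is not None:
            score = model.log_odds(left) + model.log_odds(right, reverse=True)
        else:
            score = -(ml + mr)
        hits.append(IR1Hit(i, seq_u[i : i + IR1_LEN], ml, mr, score))
    return hits


def compare_sites(
    wild: str,
    mutant: str,
    model: HalfSiteModel | None = None,
    max_mismatch_per_half: int = 1,
) -> dict[str, list[IR1Hit]]:
    """Scan a wild-type element and its mutated counterpart side by side.

    The computational analogue of a reporter assay on a wild-type vs
    mutated response element: a functional element scans as an IR1, a
    mutant with >= 2 mismatches per half site does not.
    """
    return {
        "wild_hits": scan_ir1(wild, model, max_mismatch_per_half),
        "mutant_hits": scan_ir1(mutant, model, max_mismatch_per_half),
    }


def scan_fasta_regions(
    fasta_path: str,
    regions,
    model: HalfSiteModel | None = None,
    max_mismatch_per_half: int = 1,
) -> list[tuple[str, IR1Hit]]:
    """Scan each region of a FASTA genome; hit positions stay region-relative.

    ``regions`` is any iterable of objects with ``span`` (enhancer
    windows, peaks) or bare intervals.  Returns (region_name, hit) pairs.
    """
    from pyfaidx import Fasta

    fa = Fasta(fasta_path)
    out = []
    for i, region in enumerate(regions):
        span = getattr(region, "span", region)
        name = getattr(region, "window_id",
                       getattr(region, "peak_id", f"region_{i + 1}"))
        seq = str(fa[span.chrom][span.start : span.end])
        for hit in scan_ir1(seq, model, max_mismatch_per_half):
            out.append((name, hit))
    return out


def hits_to_bed(named_hits, regions, path: str) -> None:
    """Write region-relative hits as genome-coordinate BED6.

    Score column is the hit score (-(mismatches) or PWM log-odds).
    """
    span_of = {}
    for i, region in enumerate(regions):
        name = getattr(region, "window_id",
                       getattr(region, "peak_id", f"region_{i + 1}"))
        span_of[name] = getattr(region, "span", region)
    with open(path, "w") as fh:
        for name, hit in named_hits:
            span = span_of[name]
            start = span.start + hit.position
            fh.write(
                f"{span.chrom}\t{start}\t{start + IR1_LEN}\t"
                f"{name}_ir1_{hit.position}\t{hit.score:g}\t{hit.strand}\n"
            )
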