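"""PWM construction, log-odds scanning, and motif-dependence inference.

A position weight matrix is built from a 4 x W count matrix (A, C, G, T
rows) with a pseudocount, converted to per-column probabilities and then to
log2 odds against a background composition. Scanning scores every window of
a sequence on both strands and reports hits above a fraction of the PWM's
maximum attainable score.

The dependence classifier reads the motif-occurrence fractions across the
co-binding classes of two TFs (A+B+, A+B-, A-B+) and labels the pair
independent (each TF's own-motif fraction is stable whether or not the
partner is bound), A-/B-dependent (one TF's own motif is largely absent
from the co-bound sites, which instead carry the partner's motif), or
undetermined.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

BASES = "ACGT"
_BASE_IDX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


@dataclass
class PWM:
    name: str
    counts: np.ndarray  # 4 x W, rows A,C,G,T
    pseudocount: float = 0.25
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != 4 or self.counts.shape[1] < 1:
            raise ValueError("counts must be a 4 x W matrix with W >= 1")
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")
        if not math.isclose(self.background.sum(), 1.0, rel_tol=1e-6):
            raise ValueError("background must sum to 1")
        if self.pseudocount <= 0 and (self.counts.sum(axis=0) == 0).any():
            raise ValueError("all-zero column requires pseudocount > 0")

    @property
    def width(self) -> int:
        return self.counts.shape[1]

    @property
    def probabilities(self) -> np.ndarray:
        col_tot = self.counts.sum(axis=0) + 4 * self.pseudocount
        return (self.counts + self.pseudocount) / col_tot

    @property
    def log_odds(self) -> np.ndarray:
        return np.log2(self.probabilities / self.background[:, None])

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=0).sum())

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.probabilities.argmax(axis=0))


def build_pwm(
    count_matrix: np.ndarray | Sequence[Sequence[float]],
    pseudocount: float = 0.25,
    background: Sequence[float] | None = None,
    name: str = "pwm",
) -> PWM:
    """Probability and log-odds model from a 4 x W base-count matrix."""
    bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
    return PWM(name=name, counts=np.asarray(count_matrix, float),
               pseudocount=pseudocount, background=bg)


def read_pwm(path: str | Path) -> PWM:
    """Text PWM: '>name' line then 4 rows 'A 1 2 3 ...' etc."""
    name = Path(path).stem
    rows: dict[str, list[float]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                name = line[1:].strip() or name
                continue
            parts = line.split()
            base = parts[0].upper().rstrip(":|")
            if base in _BASE_IDX:
                rows[base] = [float(x) for x in parts[1:]]
    if set(rows) != set(BASES):
        raise ValueError(f"{path}: need A, C, G and T rows")
    return build_pwm(np.array([rows[b] for b in BASES]), name=name)


def write_pwm(pwm: PWM, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f">{pwm.name}\n")
        for i, b in enumerate(BASES):
            fh.write(b + "\t" + "\t".join(f"{x:g}" for x in pwm.counts[i]) + "\n")


def _encode(seq: str) -> np.ndarray:
    """A/C/G/T -> 0..3; anything else (incl. N) -> 4."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, 4, dtype=np.int8)
    for b, i in _BASE_IDX.items():
        out[arr == ord(b)] = i
    return out


def _forward_scores(idx: np.ndarray, lo: np.ndarray) -> np.ndarray:
    """Score of every window; windows containing non-ACGT get -inf."""
    w = lo.shape[1]
    n_win = len(idx) - w + 1
    if n_win <= 0:
        return np.empty(0)
    scores = np.zeros(n_win)
    valid = np.ones(n_win, dtype=bool)
    for j in range(w):
        col = idx[j : j + n_win]
        ok = col < 4
        valid &= ok
        scores += np.where(ok, lo[np.minimum(col, 3), j], 0.0)
    scores[~valid] = -np.inf
    return scores


def scan_pwm(
    sequence: str,
    pwm: PWM,
    threshold_frac: float = 0.8,
) -> pd.DataFrame:
    """Both-strand log-odds scan.

    Hit iff score >= threshold_frac * max attainable score. Offsets are
    0-based positions of the window start on the forward sequence.
    Returns a DataFrame (offset, strand, score).
    """
    if not (0 < threshold_frac <= 1):
        raise ValueError("threshold_frac must be in (0, 1]")
    lo = pwm.log_odds
    w = pwm.width
    cutoff = threshold_frac * pwm.max_score
    hits: list[tuple[int, str, float]] = []
    if len(sequence) >= w:
        fwd = _forward_scores(_encode(sequence), lo)
        for off in np.nonzero(fwd >= cutoff)[0]:
            hits.append((int(off), "+", float(fwd[off])))
        rev = _forward_scores(_encode(revcomp(sequence)), lo)
        n = len(sequence)
        for off in np.nonzero(rev >= cutoff)[0]:
            hits.append((n - w - int(off), "-", float(rev[off])))
    out = pd.DataFrame(hits, columns=["offset", "strand", "score"])
    return out.sort_values(["offset", "strand"]).reset_index(drop=True)


def _fetch_sequence(fasta, chrom: str, start: int, end: int) -> str:
    """Slice a genome FASTA, or look up a per-peak record chrom:start-end."""
    key = f"{chrom}:{start}-{end}"
    if key in fasta:
        return str(fasta[key][:])
    if chrom not in fasta:
        raise KeyError(f"peak {key}: no FASTA record for {chrom!r}")
    record = fasta[chrom]
    if end > len(record):
        raise ValueError(f"peak {key} extends beyond {chrom} length {len(record)}")
    return str(record[start:end])


def motif_fraction_by_class(
    classes: Mapping[str, "object"],
    fasta,
    pwm: PWM,
    threshold_frac: float = 0.8,
) -> dict[str, float]:
    """Per-class fraction of peaks carrying >= 1 motif hit.

    ``fasta`` is a pyfaidx.Fasta (genome, or per-peak records named
    chrom:start-end). Empty classes report NaN rather than 0.
    """
    fractions: dict[str, float] = {}
    for label, peaks in classes.items():
        n = len(peaks)
        if n == 0:
            fractions[label] = float("nan")
            continue
        n_hit = 0
        for row in peaks.df.itertuples(index=False):
            seq = _fetch_sequence(fasta, row.chrom, int(row.start), int(row.end))
            if len(scan_pwm(seq, pwm, threshold_frac)) > 0:
                n_hit += 1
        fractions[label] = n_hit / n
    return fractions


def infer_binding_mode(
    fractions: Mapping[str, Mapping[str, float]],
    dep_ratio: float = 0.25,
    stability_margin: float = 0.25,
    flat_margin: float = 0.05,
) -> str:
    """Classify the co-binding dependence of a TF pair from motif fractions.

    ``fractions`` maps co-binding class -> {motif label -> fraction} with
    classes 'A+B+', 'A+B-', 'A-B+' and motif labels 'A' (TF A's own motif)
    and 'B'. Rules, in order:

    1. no signal — all available fractions within ``flat_margin`` of each
       other -> 'undetermined';
    2. 'B-dependent-on-A' — in co-bound sites B's own motif is largely
       absent relative to A's (ratio < ``dep_ratio``) and B's own motif is
       also low/comparable in B-only sites (the pattern where B binds via
       A's motif); mirrored for 'A-dependent-on-B';
    3. 'independent' — each TF's own-motif fraction is stable (relative
       difference < ``stability_margin``) between its co-bound and solo
       classes;
    4. otherwise 'undetermined'.
    """
    def get(cls: str, motif: str) -> float:
        return float(fractions.get(cls, {}).get(motif, float("nan")))

    fa_co, fb_co = get("A+B+", "A"), get("A+B+", "B")
    fa_solo = get("A+B-", "A")          # A's own motif where A binds alone
    fb_solo = get("A-B+", "B")          # B's own motif where B binds alone
    fa_in_bsolo = get("A-B+", "A")
    fb_in_asolo = get("A+B-", "B")

    vals = [v for v in (fa_co, fb_co, fa_solo, fb_solo, fa_in_bsolo, fb_in_asolo)
            if not math.isnan(v)]
    if not vals or math.isnan(fa_co) or math.isnan(fb_co):
        return "undetermined"
    if max(vals) - min(vals) < flat_margin:
        return "undetermined"

    def low_or_comparable(own: float, partner_there: float) -> bool:
        if math.isnan(own):
            return False
        if own < dep_ratio:
            return True
        return not math.isnan(partner_there) and own <= 2 * partner_there

    # B binds via A's motif: B's own motif depleted at co-bound sites
    if fa_co > 0 and fb_co / fa_co < dep_ratio and low_or_comparable(fb_solo, fa_in_bsolo):
        return "B-dependent-on-A"
    if fb_co > 0 and fa_co / fb_co < dep_ratio and low_or_comparable(fa_solo, fb_in_asolo):
        return "A-dependent-on-B"

    def stable(x: float, y: float) -> bool:
        if math.isnan(x) or math.isnan(y):
            return False
        m = max(x, y)
        return m == 0 or abs(x - y) / m < stability_margin

    if stable(fa_co, fa_solo) and stable(fb_co, fb_solo):
        return "independent"
    return "undetermined"
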