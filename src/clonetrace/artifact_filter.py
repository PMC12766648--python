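"""Position-weight-matrix likelihood-ratio filter for platform artifacts.

Some sequencing platforms introduce an excess of low-AAF T>G/A>C calls with
a characteristic sequence context (e.g. TTCC/GA repeats).  To remove them
without hand-picking motifs: build a position weight matrix (PWM) over the
41-base reference window around each substitution from a suspect ("test")
callset and from a clean ("control") callset, score every call by the joint
multinomial log likelihood ratio of the 9 centered bases under the two
PWMs, and filter calls whose ratio is extreme relative to the empirical
distribution of control-call ratios (p < alpha).

A>C calls are reverse-complemented into the T>G frame (substitution classes
are keyed on the pyrimidine strand), so complementary artifacts pool into
one class.
"""

from __future__ import annotations

from dataclasses import dataclass
from warnings import warn

import numpy as np
import pandas as pd

__all__ = [
    "SBSRecord",
    "PWM",
    "normalize_record",
    "build_pwm",
    "window_loglik_ratio",
    "filter_by_empirical_p",
]

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

WINDOW = 41  # reference window length stored per record
CENTER = WINDOW // 2


@dataclass(frozen=True)
class SBSRecord:
    """One single-base substitution with its reference context."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    window: str  # 41 uppercase bases, center == ref
    source: str = "test"  # "test" or "control"

    def __post_init__(self) -> None:
        if len(self.window) != WINDOW:
            raise ValueError(f"window must be {WINDOW} bases, got {len(self.window)}")
        if self.window[CENTER] != self.ref and self.window[CENTER] in _BASES:
            raise ValueError(
                f"window center {self.window[CENTER]!r} disagrees with ref {self.ref!r}"
            )

    @property
    def sbs_class(self) -> str:
        return f"{self.ref}>{self.alt}"


def normalize_record(record: SBSRecord) -> SBSRecord:
    """Flip purine-reference records onto the pyrimidine strand.

    The window is reverse-complemented so that e.g. A>C records score in the
    same T>G frame as their complements.
    """
    if record.ref in "CT":
        return record
    return SBSRecord(
        chrom=record.chrom,
        pos=record.pos,
        ref=record.ref.translate(_COMPLEMENT),
        alt=record.alt.translate(_COMPLEMENT),
        window=record.window.translate(_COMPLEMENT)[::-1],
        source=record.source,
    )


@dataclass
class PWM:
    """Per-position base probabilities over a fixed window.

    ``probs`` is (window length, 4) over A,C,G,T; each row sums to 1.
    Masked (non-ACGT) bases were excluded from the column counts.
    """

    probs: np.ndarray
    pseudocount: float
    sbs_class: str
    source: str

    def __post_init__(self) -> None:
        rowsums = self.probs.sum(axis=1)
        if not np.allclose(rowsums, 1.0, atol=1e-9):
            raise ValueError("PWM columns must sum to 1")


def build_pwm(
    records: list[SBSRecord],
    sbs_class: str | None = None,
    pseudocount: float = 0.5,
) -> PWM:
    """Count-based PWM from the records' 41-base windows.

    Column probability = (count + pseudocount) / (n_effective + 4*pseudocount)
    where n_effective counts only unmasked (ACGT) bases at that position.
    """
    recs = [normalize_record(r) for r in records]
    if sbs_class is not None:
        recs = [r for r in recs if r.sbs_class == sbs_class]
    if not recs:
        raise ValueError(f"no records of class {sbs_class!r}")
    counts = np.zeros((WINDOW, 4))
    for r in recs:
        for j, base in enumerate(r.window):
            k = _BASE_INDEX.get(base)
            if k is not None:
                counts[j, k] += 1
    denom = counts.sum(axis=1, keepdims=True) + 4.0 * pseudocount
    probs = (counts + pseudocount) / denom
    return PWM(
        probs=probs,
        pseudocount=pseudocount,
        sbs_class=sbs_class or recs[0].sbs_class,
        source=recs[0].source,
    )


def window_loglik_ratio(
    record: SBSRecord,
    test_pwm: PWM,
    control_pwm: PWM,
    window_half_width: int = 4,
) -> float:
    """Joint multinomial log likelihood ratio over the centered window.

    Sums log p_test(base) - log p_control(base) over the 2*half_width+1
    positions centered on the substitution; masked bases are skipped.
    """
    rec = normalize_record(record)
    lr = 0.0
    for j in range(CENTER - window_half_width, CENTER + window_half_width + 1):
        k = _BASE_INDEX.get(rec.window[j])
        if k is None:
            continue
        pt = test_pwm.probs[j, k]
        pc = control_pwm.probs[j, k]
        if pt == 0.0 or pc == 0.0:
            raise ZeroDivisionError(
                "zero PWM probability encountered; use a positive pseudocount"
            )
        lr += float(np.log(pt) - np.log(pc))
    return lr


def _class_counts(records: list[SBSRecord]) -> np.ndarray:
    counts = np.zeros((WINDOW, 4))
    for r in records:
        for j, base in enumerate(r.window):
            k = _BASE_INDEX.get(base)
            if k is not None:
                counts[j, k] += 1
    return counts


def _score_loo(
    record: SBSRecord,
    t_counts: np.ndarray,
    c_counts: np.ndarray,
    pseudocount: float,
    half_width: int,
    own: str | None,
) -> float:
    """Centered log LR with the record's own window left out of the PWM it
    contributed to (removes self-inclusion bias, keeping test and control
    scores exchangeable under the null)."""
    lr = 0.0
    for j in range(CENTER - half_width, CENTER + half_width + 1):
        k = _BASE_INDEX.get(record.window[j])
        if k is None:
            continue
        tc = t_counts[j].copy()
        cc = c_counts[j].copy()
        if own == "test":
            tc[k] -= 1
        elif own == "control":
            cc[k] -= 1
        pt = (tc[k] + pseudocount) / (tc.sum() + 4.0 * pseudocount)
        pc = (cc[k] + pseudocount) / (cc.sum() + 4.0 * pseudocount)
        if pt <= 0.0 or pc <= 0.0:
            raise ZeroDivisionError(
                "zero PWM probability encountered; use a positive pseudocount"
            )
        lr += float(np.log(pt) - np.log(pc))
    return lr


def filter_by_empirical_p(
    test_records: list[SBSRecord],
    control_records: list[SBSRecord],
    alpha: float = 0.05,
    pseudocount: float = 0.5,
    window_half_width: int = 4,
) -> tuple[list[SBSRecord], list[SBSRecord], pd.DataFrame]:
    """Empirical-p filter of test records against the control callset.

    Per substitution class (pyrimidine frame): PWMs are built from test and
    control windows and every record is scored by the centered log
    likelihood ratio, leaving the record's own window out of its source PWM
    (without this the test set's own records score inflated ratios and the
    filter is anticonservative at modest callset sizes).  The null
    distribution is the control records' ratios and
    p = (1 + #{control LR >= observed LR}) / (n_control + 1).  Test records
    with p < alpha are removed as artifacts.
    """
    if not test_records or not control_records:
        raise ValueError("both test and control record sets must be non-empty")
    test_n = [normalize_record(r) for r in test_records]
    ctrl_n = [normalize_record(r) for r in control_records]
    classes = sorted({r.sbs_class for r in test_n})
    kept: list[SBSRecord] = []
    removed: list[SBSRecord] = []
    rows = []
    for cls in classes:
        t_cls = [r for r in test_n if r.sbs_class == cls]
        c_cls = [r for r in ctrl_n if r.sbs_class == cls]
        orig = [r for r, rn in zip(test_records, test_n) if rn.sbs_class == cls]
        if not c_cls:
            warn(f"no control records for class {cls}; keeping all {len(t_cls)}")
            kept.extend(orig)
            for r in t_cls:
                rows.append((r.chrom, r.pos, cls, np.nan, np.nan, True))
            continue
        if len(c_cls) < 20:
            warn(
                f"only {len(c_cls)} control records for class {cls}; "
                "empirical p resolution is coarse"
            )
        t_counts = _class_counts(t_cls)
        c_counts = _class_counts(c_cls)
        null_lrs = np.array(
            [
                _score_loo(r, t_counts, c_counts, pseudocount, window_half_width, "control")
                for r in c_cls
            ]
        )
        for r, ro in zip(t_cls, orig):
            lr = _score_loo(r, t_counts, c_counts, pseudocount, window_half_width, "test")
            p = (1.0 + np.sum(null_lrs >= lr)) / (len(null_lrs) + 1.0)
            keep = p >= alpha
            (kept if keep else removed).append(ro)
            rows.append((r.chrom, r.pos, cls, lr, p, keep))
    pvals = pd.DataFrame(
        rows, columns=["chrom", "pos", "sbs_class", "loglik_ratio", "p_value", "kept"]
    )
    return kept, removed, pvals
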