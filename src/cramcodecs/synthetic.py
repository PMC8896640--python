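"""Seeded generators for codec-shaped test data.

Three quality regimes are emulated, matching the instrument classes whose
data the codecs target:

* **NovaSeq-like** — 4 discrete Phred values (2, 12, 23, 37) produced by
  thresholding a latent per-read quality level that follows a smooth random
  walk.  Good clusters sit deep inside the top bin, yielding the very long
  q37 runs that make RLE and PACK productive; a minority of low-quality
  clusters hover near bin boundaries, producing bursty mixed stretches
  whose structure extends beyond one symbol of context (which is what the
  context-model quality codec exploits over a static order-1 coder);
* **HiSeq-2000-like** — 40 discrete values (2..41) from a smooth
  random-walk chain with a per-cycle degradation effect (qualities decay
  toward late cycles, plus a few deliberately bad cycles);
* **PacBio-CLR-like** — the full 0..93 range drawn i.i.d. from a broad
  marginal, so successive values are essentially uncorrelated and the data
  is nearly incompressible.

Read names follow the classic Illumina layout
``<instrument>:<run>:<flowcell>:<lane>:<tile>:<x>:<y>`` with fixed-width
numeric coordinates advancing monotonically, so the name-sorted order is
also lexicographic; "position-scrambled" order applies a seeded
permutation of the sorted list, standing in for coordinate-sorted
alignments.  All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fqzcomp import QualityRecord

__all__ = [
    "QualityProfile",
    "NameProfile",
    "novaseq_profile",
    "hiseq_profile",
    "pacbio_profile",
    "gen_qualities",
    "gen_names",
    "quality_lines",
    "parse_quality_lines",
    "records_to_bytes",
    "write_fastq",
]


@dataclass
class LatentWalk:
    """Binned-latent-level quality model (RTA3-style quantization).

    A per-read latent quality level follows a Gaussian random walk and the
    emitted value is the bin the level falls in.  Reads deep inside a bin
    emit long constant runs; reads hovering near a threshold emit bursty
    mixtures whose statistics depend on more than the single previous
    value — the kind of structure context-model quality codecs exploit.
    """

    thresholds: tuple[float, ...] = (3.0, 8.0, 20.0)  # bin upper bounds
    level_max: float = 30.0
    start_good: tuple[float, float] = (27.0, 2.0)  # mean, sd of latent start
    start_bad: tuple[float, float] = (14.0, 5.0)
    vol_good: float = 0.4  # per-cycle walk standard deviation
    vol_bad: float = 1.6
    bad_fraction: float = 0.25
    drift: float = -0.02  # per-cycle downward drift, in units of volatility


@dataclass
class QualityProfile:
    """Description of one quality regime.

    Either a first-order Markov chain over the alphabet (``transition`` /
    ``initial``) or a binned latent-level walk (``latent``).
    """

    alphabet: list[int]
    transition: np.ndarray | None  # rows: current symbol index -> next pmf
    initial: np.ndarray | None  # pmf of the first symbol of a record
    n_records: int
    record_length: int
    seed: int
    latent: LatentWalk | None = None
    position_effect: np.ndarray | None = None  # per-cycle degradation prob
    position_effect_alt: np.ndarray | None = None  # read-2 cycle profile
    transition_alt: np.ndarray | None = None  # odd records (read-2 style)
    transition_bad: np.ndarray | None = None  # low-quality record sub-population
    bad_fraction: float = 0.0
    paired: bool = False  # odd records come from a noisier read-2 population
    dup_fraction: float = 0.0
    reverse_fraction: float = 0.0

    def validate(self) -> None:
        k = len(self.alphabet)
        if self.latent is not None:
            if len(self.latent.thresholds) != k - 1:
                raise ValueError("latent walk needs one threshold per bin boundary")
            return
        if self.transition is None or self.initial is None:
            raise ValueError("profile needs either a transition matrix or a latent walk")
        if self.transition.shape != (k, k):
            raise ValueError("transition matrix shape must match the alphabet")
        if not np.allclose(self.transition.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("transition rows must sum to 1")
        if not np.isclose(self.initial.sum(), 1.0, atol=1e-9):
            raise ValueError("initial distribution must sum to 1")
        if self.transition_alt is not None and not np.allclose(
            self.transition_alt.sum(axis=1), 1.0, atol=1e-9
        ):
            raise ValueError("alternate transition rows must sum to 1")


def novaseq_profile(
    n_records: int = 10000,
    record_length: int = 100,
    seed: int = 1,
    paired: bool = False,
    dup_fraction: float = 0.0,
) -> QualityProfile:
    """4-value run-rich regime (binned Phred 2/12/23/37, dominated by 37).

    Good clusters hold a latent level deep inside the top bin, so most reads
    are long q37 runs; about a quarter of clusters are low quality and
    hover around the bin thresholds, emitting bursty mixed stretches.  The
    default corpus size (10000 reads of 100 cycles, ~1 MB of quality
    values) matches the block size at which the block codecs are normally
    compared.
    """
    return QualityProfile(
        alphabet=[2, 12, 23, 37],
        transition=None,
        initial=None,
        n_records=n_records,
        record_length=record_length,
        seed=seed,
        latent=LatentWalk(),
        paired=paired,
        dup_fraction=dup_fraction,
    )


def hiseq_profile(
    n_records: int = 1000, record_length: int = 100, seed: int = 1,
    paired: bool = False,
) -> QualityProfile:
    """40-value regime: smooth quality random walk plus bad cycles.

    With ``paired``, read-2 records (odd indices) suffer several additional
    severely erroneous cycles that read-1 records do not — the situation
    where splitting the context model by a read-1/read-2 selector bit pays
    off, since no amount of quality history predicts a cycle-specific error.
    """
    k = 40
    idx = np.arange(k)
    t = np.exp(-np.abs(idx[:, None] - idx[None, :]) / 3.0)
    t /= t.sum(axis=1, keepdims=True)
    init = np.exp(-np.abs(idx - 32) / 6.0)
    init /= init.sum()
    effect = np.minimum(0.25, 0.002 * np.arange(record_length))
    for bad in (record_length // 3, (4 * record_length) // 5):
        if bad < record_length:
            effect[bad] = 0.35
    effect_alt = None
    if paired:
        # read 1 stays nearly clean while read 2 suffers dense scattered
        # erroneous cycles (quality recovers between them, so history never
        # predicts the next miscall) — the regime where a read-1/read-2
        # selector bit pays for itself
        effect = np.minimum(0.02, 0.0002 * np.arange(record_length))
        effect_alt = effect.copy()
        for bad in range(record_length // 12, record_length, 2):
            effect_alt[bad] = 0.55
    return QualityProfile(
        alphabet=list(range(2, 42)),
        transition=t,
        initial=init,
        n_records=n_records,
        record_length=record_length,
        seed=seed,
        position_effect=effect,
        position_effect_alt=effect_alt,
        paired=paired,
    )


def pacbio_profile(
    n_records: int = 200, record_length: int = 500, seed: int = 1
) -> QualityProfile:
    """0..93 range, i.i.d. draws: near-zero lag-1 autocorrelation."""
    k = 94
    idx = np.arange(k)
    marginal = np.exp(-0.5 * ((idx - 45) / 18.0) ** 2)
    marginal = np.maximum(marginal / marginal.sum(), 2e-4)
    marginal /= marginal.sum()
    t = np.tile(marginal, (k, 1))
    return QualityProfile(
        alphabet=list(range(k)),
        transition=t,
        initial=marginal,
        n_records=n_records,
        record_length=record_length,
        seed=seed,
    )


def _gen_latent_states(profile: QualityProfile, rng, use_alt) -> np.ndarray:
    """Emit bin indices from the latent-level walk."""
    lw = profile.latent
    n, length = profile.n_records, profile.record_length
    is_bad = rng.random(n) < lw.bad_fraction
    mean = np.where(is_bad, lw.start_bad[0], lw.start_good[0])
    sd = np.where(is_bad, lw.start_bad[1], lw.start_good[1])
    lvl = np.clip(rng.normal(mean, sd), 0.0, lw.level_max)
    vol = np.where(is_bad, lw.vol_bad, lw.vol_good)
    crash = np.zeros(n)
    if profile.paired:
        # read-2 clusters are slightly noisier and crash in the second half
        # of the read, the way second reads degrade late on-instrument; early
        # cycles look like read 1, so recent history alone cannot tell the
        # populations apart and the selector bit carries real information
        vol = np.where(use_alt, vol * 1.3, vol)
        crash = np.where(use_alt, 0.35, 0.0)
    thr = np.asarray(lw.thresholds)
    out = np.empty((n, length), dtype=np.int64)
    for c in range(length):
        out[:, c] = np.searchsorted(thr, lvl, side="left")
        step = rng.normal(0.0, 1.0, n) * vol + lw.drift * vol
        if c >= length // 2:
            step = step - crash
        lvl = np.clip(lvl + step, 0.0, lw.level_max)
    return out


def _gen_markov_states(profile: QualityProfile, rng, use_alt) -> np.ndarray:
    """Evolve the first-order chain, vectorized across records."""
    n, length = profile.n_records, profile.record_length
    k = len(profile.alphabet)
    cum = np.cumsum(profile.transition, axis=1)
    cum_init = np.cumsum(profile.initial)

    # per-record transition choice: 0 = main, 1 = read-2 alternative, 2 = bad
    matrix_of = np.zeros(n, dtype=np.int64)
    matrix_of[use_alt] = 1
    if profile.transition_bad is not None and profile.bad_fraction > 0:
        is_bad = rng.random(n) < profile.bad_fraction
        matrix_of[is_bad & ~use_alt] = 2
    cums = [cum,
            np.cumsum(profile.transition_alt, axis=1) if profile.transition_alt is not None else cum,
            np.cumsum(profile.transition_bad, axis=1) if profile.transition_bad is not None else cum]

    states = np.empty((n, length), dtype=np.int64)
    states[:, 0] = np.searchsorted(cum_init, rng.random(n), side="right")
    for c in range(1, length):
        u = rng.random(n)
        nxt = np.empty(n, dtype=np.int64)
        for mi in range(3):
            sel = matrix_of == mi
            if not sel.any():
                continue
            nxt[sel] = (u[sel, None] > cums[mi][states[sel, c - 1]]).sum(axis=1)
        states[:, c] = nxt
    np.clip(states, 0, k - 1, out=states)

    if profile.position_effect is not None:
        # cycle-specific miscalls replace the emitted value only; the
        # underlying cluster quality (the chain state) recovers immediately
        low = max(1, k // 4)
        alt = profile.position_effect_alt
        emitted = states.copy()
        for c in range(min(length, len(profile.position_effect))):
            p = float(profile.position_effect[c])
            prob = np.full(n, p)
            if alt is not None and c < len(alt):
                prob[use_alt] = float(alt[c])
            if not prob.any():
                continue
            hit = rng.random(n) < prob
            emitted[hit, c] = rng.integers(0, low, size=int(hit.sum()))
        states = emitted
    return states


def gen_qualities(profile: QualityProfile) -> list[QualityRecord]:
    """Draw quality records from the profile, deterministically in its seed."""
    profile.validate()
    rng = np.random.default_rng(profile.seed)
    n = profile.n_records
    use_alt = (
        (np.arange(n) % 2 == 1)
        if (profile.paired or profile.transition_alt is not None)
        else np.zeros(n, dtype=bool)
    )
    if profile.latent is not None:
        states = _gen_latent_states(profile, rng, use_alt)
    else:
        states = _gen_markov_states(profile, rng, use_alt)

    alpha = np.asarray(profile.alphabet)
    quals = alpha[states]

    dup = (
        rng.random(n) < profile.dup_fraction
        if profile.dup_fraction > 0
        else np.zeros(n, dtype=bool)
    )
    rev = (
        rng.random(n) < profile.reverse_fraction
        if profile.reverse_fraction > 0
        else np.zeros(n, dtype=bool)
    )
    records: list[QualityRecord] = []
    for i in range(n):
        sel = int(use_alt[i])
        if i > 0 and dup[i]:
            records.append(
                QualityRecord(records[-1].quals, bool(rev[i]), True, sel)
            )
        else:
            records.append(
                QualityRecord(tuple(int(q) for q in quals[i]), bool(rev[i]), False, sel)
            )
    return records


# ---------------------------------------------------------------------------
# Read names.
# ---------------------------------------------------------------------------

@dataclass
class NameProfile:
    """Illumina-style name template with monotone tile/x/y counters."""

    n_names: int
    order: str = "name_sorted"  # or "position_scrambled"
    seed: int = 1
    instrument: str = "HSQ1004"
    run: int = 134
    flowcell: str = "C0D8DACXX"
    lane: int = 4

    def __post_init__(self) -> None:
        if self.order not in ("name_sorted", "position_scrambled"):
            raise ValueError(f"unknown name order {self.order!r}")


def gen_names(profile: NameProfile) -> list[str]:
    """Generate read names; sorted output is lexicographically non-decreasing.

    The numeric coordinates keep fixed decimal widths (tile 4, x 5, y 6
    digits) so lexicographic and numeric order agree, and every step changes
    at most two numeric fields — mirroring how consecutive name-sorted reads
    from one flowcell differ only in their trailing coordinates.
    """
    rng = np.random.default_rng(profile.seed)
    prefix = f"{profile.instrument}:{profile.run}:{profile.flowcell}:{profile.lane}"
    tile, x, y = 1101, 20375, 180666
    names: list[str] = []
    for _ in range(profile.n_names):
        names.append(f"{prefix}:{tile}:{x}:{y}")
        dy = int(rng.integers(1, 38))
        if y + dy > 999999 or rng.random() < 0.10:
            dx = int(rng.integers(1, 10))
            if x + dx > 99999:
                tile += 1
                x = 10000
            else:
                x += dx
                y = int(rng.integers(100000, 1000000))
        else:
            y += dy
    if profile.order == "position_scrambled":
        perm = rng.permutation(profile.n_names)
        names = [names[i] for i in perm]
    return names


# ---------------------------------------------------------------------------
# Line-oriented / FASTQ helpers.
# ---------------------------------------------------------------------------

def quality_lines(records: list[QualityRecord]) -> str:
    """Render records as one Phred+33 ASCII string per line."""
    return "\n".join("".join(chr(q + 33) for q in r.quals) for r in records) + "\n"


def parse_quality_lines(text: str) -> list[QualityRecord]:
    """Parse Phred+33 lines back into plain records (no flags)."""
    records = []
    for line in text.splitlines():
        if not line:
            continue
        quals = []
        for ch in line:
            q = ord(ch) - 33
            if q < 0 or q > 93:
                raise ValueError(f"character {ch!r} is not a valid Phred+33 quality")
            quals.append(q)
        records.append(QualityRecord(tuple(quals)))
    return records


def records_to_bytes(records: list[QualityRecord]) -> bytes:
    """Concatenate raw quality values into one byte block (no separators)."""
    return bytes(q for r in records for q in r.quals)


def write_fastq(names: list[str], records: list[QualityRecord]) -> str:
    """Minimal FASTQ text (sequences are runs of N) for end-to-end tests."""
    if len(names) != len(records):
        raise ValueError("names and records must have equal length")
    chunks = []
    for name, rec in zip(names, records):
        qual = "".join(chr(q + 33) for q in rec.quals)
        chunks.append(f"@{name}\n{'N' * rec.length}\n+\n{qual}\n")
    return "".join(chunks)
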