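"""Generative simulator of blocked-rRNA capture sequencing.

The model follows the causal chain of the wet-lab chemistry:

1. A molecule is drawn from the total-RNA pool in proportion to class
   abundance (default ~95% rRNA) times a per-gene weight.
2. Its capturable 3' end ``E`` is either the native 3' terminus (probability
   ``1 - frag_rate``) or a fragment 3' end.  Fragment-derived reads
   concentrate at read-start *hotspots*: with a hotspot component the read
   start is planted at the hotspot coordinate (± uniform jitter) and the
   fragment extends a further ``d`` nt downstream of the read, with ``d``
   drawn from the fragment-length mixture; the remaining fragment mass is a
   uniform background along the transcript.
3. Poly-A tailing/capture succeeds with probability
   ``polyA_baseline[class] * (1 - beta)`` when a blocking-primer interval
   contains ``E`` within ``block_tolerance`` nt (``beta`` = blocker
   efficiency; the strongest overlapping blocker wins), else with the bare
   baseline.  Rejected molecules are redrawn until ``n_reads`` are emitted,
   mirroring the lab's fixed sequencing depth.
4. The right mate is ``read_len`` consecutive sense-strand bases ending
   within the fragment, with per-base substitution errors; the left mate is
   the 6-nt sample barcode followed by a poly-T stretch.

Because step 3 is plain rejection sampling, the emitted class composition has
the closed form  f_c = sum_{t in c} a_t p_t / sum_t a_t p_t  with
``a_t`` the pool weight and ``p_t`` the per-transcript capture probability;
:func:`expected_class_fractions` evaluates it exactly from the discrete
distribution of ``E``, and is the oracle used to calibrate presets and test
the simulator.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from embrseq.config import Blocker, HotspotSpec, SimConfig
from embrseq.reference import ReferenceRecord, ReferenceSet

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_TO_NUM = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_TO_NUM[_b] = _i

# paper-scale rRNA names used by presets
RRNA_IDS = ("rRNA_5S", "rRNA_16S", "rRNA_23S")

CANONICAL_HOTSPOTS = {
    "rRNA_16S": (107, 682, 1241),
    "rRNA_23S": (375, 1421, 1641),
}


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return bytes(_BASES[rng.integers(0, 4, size=length)]).decode()


# ----------------------------------------------------------------- reference


def build_reference(config: SimConfig) -> ReferenceSet:
    """Build a synthetic annotated transcriptome under ``config``.

    Three rRNA records with 5S/16S/23S-like lengths, ``n_tRNA`` tRNAs and
    ``n_mRNA`` mRNAs, with sequences drawn deterministically from
    ``config.seed``.
    """
    config.validate()
    if len(config.rRNA_lengths) != 3:
        raise ValueError("expected exactly three rRNA lengths (5S/16S/23S-like)")
    rng = np.random.default_rng([config.seed, 0])
    records: list[ReferenceRecord] = []
    for ref_id, length in zip(RRNA_IDS, config.rRNA_lengths):
        records.append(ReferenceRecord(ref_id, _random_seq(rng, length), "rRNA", ref_id))
    for i in range(config.n_tRNA):
        records.append(
            ReferenceRecord(f"tRNA_{i:03d}", _random_seq(rng, config.tRNA_length), "tRNA", f"tRNA_{i:03d}")
        )
    lo, hi = config.mRNA_length_range
    for i in range(config.n_mRNA):
        length = int(rng.integers(lo, hi + 1))
        records.append(ReferenceRecord(f"gene_{i:04d}", _random_seq(rng, length), "mRNA", f"gene_{i:04d}"))
    return ReferenceSet(records)


def gene_weights(ref: ReferenceSet, config: SimConfig) -> np.ndarray:
    """Within-class relative weight of each reference, deterministic under the seed.

    rRNA weight is proportional to transcript length, tRNAs are uniform, and
    mRNA gene weights are log-normal with shape ``per_gene_sigma`` —
    reproducing the orders-of-magnitude spread of bacterial expression.
    Weights are normalized to sum to 1 within each class.
    """
    rng = np.random.default_rng([config.seed, 1])
    w = np.zeros(len(ref))
    mrna_draws = rng.lognormal(mean=0.0, sigma=config.per_gene_sigma, size=len(ref))
    for i, rec in enumerate(ref):
        if rec.class_label == "rRNA":
            w[i] = len(rec)
        elif rec.class_label == "tRNA":
            w[i] = 1.0
        else:
            w[i] = mrna_draws[i]
    for cls in ("rRNA", "tRNA", "mRNA"):
        mask = np.array([rec.class_label == cls for rec in ref])
        total = w[mask].sum()
        if total > 0:
            w[mask] /= total
    return w


# ------------------------------------------------------ per-reference model


def _d_distribution(config: SimConfig) -> np.ndarray:
    """P(fragment 3' end lies d nt downstream of the read end), d = 0..fmax-R."""
    fmin, fmax = config.fragment_len
    R = config.read_len
    nL = fmax - fmin + 1
    probs = np.zeros(fmax - R + 1)
    for Lf in range(fmin, fmax + 1):
        probs[: Lf - R + 1] += 1.0 / (nL * (Lf - R + 1))
    return probs


@dataclass
class _RefModel:
    """Precomputed E-distribution, blocker profile and samplers for one reference."""

    record: ReferenceRecord
    seq_num: np.ndarray          # uint8 base codes
    p_end: np.ndarray            # P(E = x), 0-based x
    beta_at: np.ndarray          # suppression efficiency at each 0-based 3'-end position
    comp_probs: np.ndarray       # [native, uniform, hotspot_1, ...]
    hotspot_coords: list[int]    # 0-based planted read starts
    capture_given_polyA: float   # sum_x P(E=x) (1 - beta_at[x])


def _build_ref_model(rec: ReferenceRecord, config: SimConfig, d_probs: np.ndarray) -> _RefModel:
    L = len(rec)
    R = config.read_len
    if R > L:
        raise ValueError(f"read_len {R} exceeds reference {rec.ref_id!r} length {L}")
    hotspots = [h for h in config.hotspots if h.ref_id == rec.ref_id]
    for h in hotspots:
        if h.coordinate > L:
            raise ValueError(
                f"hotspot coordinate {h.coordinate} outside reference {rec.ref_id!r} (length {L})"
            )
    delta = config.frag_rate
    w_hot = np.array([h.weight for h in hotspots], dtype=float)
    w_tot = config.frag_uniform_weight + w_hot.sum()
    if delta > 0 and w_tot <= 0:
        raise ValueError("fragment mode requires positive hotspot or uniform weight")

    comp_probs = np.zeros(2 + len(hotspots))
    comp_probs[0] = 1.0 - delta
    if delta > 0:
        comp_probs[1] = delta * config.frag_uniform_weight / w_tot
        comp_probs[2:] = delta * w_hot / w_tot

    # discrete distribution of the capturable 3' end E (0-based)
    p_end = np.zeros(L)
    p_end[L - 1] += comp_probs[0]
    n_uniform = L - (R - 1)
    if comp_probs[1] > 0:
        p_end[R - 1 :] += comp_probs[1] / n_uniform
    tau = config.hotspot_jitter
    n_j = 2 * tau + 1
    for h, w in zip(hotspots, comp_probs[2:]):
        if w == 0:
            continue
        for j in range(-tau, tau + 1):
            s = min(max(h.coordinate - 1 + j, 0), L - R)
            base = s + R - 1
            for d, pd in enumerate(d_probs):
                p_end[min(base + d, L - 1)] += w * pd / n_j

    beta_at = np.zeros(L)
    tol = config.block_tolerance
    for b in config.blockers:
        if b.ref_id != rec.ref_id:
            continue
        if b.end > L:
            raise ValueError(f"blocker interval {b.start}-{b.end} outside {rec.ref_id!r}")
        lo = max(b.start - 1 - tol, 0)
        hi = min(b.end - 1 + tol, L - 1)
        beta_at[lo : hi + 1] = np.maximum(beta_at[lo : hi + 1], b.beta)

    capture = float(np.dot(p_end, 1.0 - beta_at))
    seq_num = _BASE_TO_NUM[np.frombuffer(rec.sequence.encode(), dtype=np.uint8)]
    return _RefModel(rec, seq_num, p_end, beta_at, comp_probs,
                     [h.coordinate - 1 for h in hotspots], capture)


def _build_models(ref: ReferenceSet, config: SimConfig) -> list[_RefModel]:
    if config.read_len > min(len(r) for r in ref):
        shortest = min(ref, key=len)
        raise ValueError(
            f"read_len {config.read_len} exceeds shortest reference "
            f"{shortest.ref_id!r} ({len(shortest)} nt)"
        )
    for h in config.hotspots:
        if h.ref_id not in ref:
            raise ValueError(f"hotspot references unknown ref_id {h.ref_id!r}")
    for b in config.blockers:
        if b.ref_id not in ref:
            raise ValueError(f"blocker references unknown ref_id {b.ref_id!r}")
    d_probs = _d_distribution(config)
    return [_build_ref_model(rec, config, d_probs) for rec in ref]


# ----------------------------------------------------------- closed form


def expected_class_fractions(ref: ReferenceSet, config: SimConfig) -> dict[str, float]:
    """Exact expected class composition of emitted reads under rejection sampling."""
    models = _build_models(ref, config)
    w = gene_weights(ref, config)
    contrib: dict[str, float] = {"rRNA": 0.0, "tRNA": 0.0, "mRNA": 0.0}
    for model, wi in zip(models, w):
        cls = model.record.class_label
        a = config.class_abundance[cls] * wi
        contrib[cls] += a * config.polyA_baseline[cls] * model.capture_given_polyA
    total = sum(contrib.values())
    if total == 0:
        raise ValueError("no molecule can be captured under this configuration")
    return {cls: v / total for cls, v in contrib.items()}


def expected_rrna_fraction(ref: ReferenceSet, config: SimConfig) -> float:
    return expected_class_fractions(ref, config)["rRNA"]


# ----------------------------------------------------------- read simulation


def _sample_positions(model: _RefModel, m: int, config: SimConfig, rng: np.random.Generator):
    """Draw m (read_start, E) pairs from one reference's generative components."""
    L = len(model.record)
    R = config.read_len
    fmin, fmax = config.fragment_len
    comp = rng.choice(len(model.comp_probs), size=m, p=model.comp_probs)
    Lf = rng.integers(fmin, fmax + 1, size=m)
    E = np.empty(m, dtype=np.int64)
    s = np.empty(m, dtype=np.int64)

    end_mask = comp <= 1
    n_end = int(end_mask.sum())
    if n_end:
        E_end = np.where(comp[end_mask] == 0, L - 1,
                         rng.integers(R - 1, L, size=n_end))
        lo = np.maximum(R - 1, E_end - (Lf[end_mask] - R))
        e = lo + np.floor(rng.random(n_end) * (E_end - lo + 1)).astype(np.int64)
        E[end_mask] = E_end
        s[end_mask] = e - R + 1

    tau = config.hotspot_jitter
    for k, c0 in enumerate(model.hotspot_coords):
        mask = comp == k + 2
        n_h = int(mask.sum())
        if not n_h:
            continue
        j = rng.integers(-tau, tau + 1, size=n_h)
        s_h = np.clip(c0 + j, 0, L - R)
        d = Lf[mask] - R  # max downstream extent for each drawn fragment
        d_draw = np.floor(rng.random(n_h) * (d + 1)).astype(np.int64)
        E[mask] = np.minimum(s_h + R - 1 + d_draw, L - 1)
        s[mask] = s_h
    return s, E


def simulate_reads(
    ref: ReferenceSet, config: SimConfig
) -> tuple[list["np.ndarray"], pd.DataFrame]:
    """Simulate ``config.n_reads`` captured paired-end reads.

    Returns ``(pairs, truth)`` where ``pairs`` is a list of
    ``(read_id, left_seq, right_seq)`` tuples and ``truth`` a DataFrame with
    one row per emitted read: ``read_id, ref_id, class, read_start`` (0-based),
    ``read_end`` (0-based exclusive) and ``three_prime_end`` (1-based capturable
    3' end).  Deterministic and byte-stable under ``(config, seed)``.
    """
    models = _build_models(ref, config)
    w = gene_weights(ref, config)
    prior = np.array(
        [config.class_abundance[m.record.class_label] * wi for m, wi in zip(models, w)]
    )
    if prior.sum() == 0:
        raise ValueError("all pool weights are zero")
    prior = prior / prior.sum()
    polyA = np.array([config.polyA_baseline[m.record.class_label] for m in models])
    p_accept = float(np.dot(prior, polyA * np.array([m.capture_given_polyA for m in models])))
    if p_accept == 0:
        raise ValueError("no molecule can be captured under this configuration")

    rng = np.random.default_rng([config.seed, 2])
    R = config.read_len
    acc_ref: list[np.ndarray] = []
    acc_s: list[np.ndarray] = []
    acc_E: list[np.ndarray] = []
    n_acc = 0
    while n_acc < config.n_reads:
        batch = max(2048, int((config.n_reads - n_acc) / p_accept * 1.25))
        ref_idx = rng.choice(len(models), size=batch, p=prior)
        b_ord, b_ref, b_s, b_E = [], [], [], []
        for ri in range(len(models)):
            mask = ref_idx == ri
            m = int(mask.sum())
            if not m:
                continue
            model = models[ri]
            s, E = _sample_positions(model, m, config, rng)
            u = rng.random(m)
            keep = u < polyA[ri] * (1.0 - model.beta_at[E])
            if keep.any():
                b_ord.append(np.flatnonzero(mask)[keep])
                b_ref.append(np.full(int(keep.sum()), ri))
                b_s.append(s[keep])
                b_E.append(E[keep])
        if not b_ord:
            continue
        # restore the batch's molecule draw order so truncation at n_reads
        # cannot bias the emitted composition toward any reference
        order = np.argsort(np.concatenate(b_ord), kind="stable")
        acc_ref.append(np.concatenate(b_ref)[order])
        acc_s.append(np.concatenate(b_s)[order])
        acc_E.append(np.concatenate(b_E)[order])
        n_acc += order.size

    ref_arr = np.concatenate(acc_ref)[: config.n_reads]
    s_arr = np.concatenate(acc_s)[: config.n_reads]
    E_arr = np.concatenate(acc_E)[: config.n_reads]
    n = config.n_reads

    # right-mate sequences with substitution errors
    right = np.empty((n, R), dtype=np.uint8)
    for ri, model in enumerate(models):
        mask = ref_arr == ri
        if mask.any():
            idx = s_arr[mask, None] + np.arange(R)[None, :]
            right[mask] = model.seq_num[idx]
    if config.error_rate > 0:
        err = rng.random((n, R)) < config.error_rate
        shift = rng.integers(1, 4, size=(n, R))
        right = np.where(err, (right + shift) % 4, right)
    right_seqs = [bytes(_BASES[row]).decode() for row in right]

    left_seq = (config.barcode + "T" * 18).ljust(R, "T")[:R]
    ref_ids = [models[ri].record.ref_id for ri in ref_arr]
    classes = [models[ri].record.class_label for ri in ref_arr]
    read_ids = [f"read{i:07d}" for i in range(n)]
    pairs = [(rid, left_seq, rseq) for rid, rseq in zip(read_ids, right_seqs)]
    truth = pd.DataFrame(
        {
            "read_id": read_ids,
            "ref_id": ref_ids,
            "class": classes,
            "read_start": s_arr,
            "read_end": s_arr + R,
            "three_prime_end": E_arr + 1,
        }
    )
    return pairs, truth


# ----------------------------------------------------------------- file I/O


def write_paired_fastq(
    pairs: Iterable[tuple[str, str, str]], r1_path: str | Path, r2_path: str | Path
) -> None:
    """Write 4-line FASTQ mates with /1 and /2 read-name suffixes (constant quality)."""
    with open(r1_path, "w") as f1, open(r2_path, "w") as f2:
        for read_id, left, right in pairs:
            f1.write(f"@{read_id}/1\n{left}\n+\n{'I' * len(left)}\n")
            f2.write(f"@{read_id}/2\n{right}\n+\n{'I' * len(right)}\n")


def write_truth(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, sep="\t", index=False)


# ------------------------------------------------------------------ presets

CONTROL_FRACTIONS = {"rRNA": 0.64, "tRNA": 0.0037}
EMBR_RRNA_FRACTION = 0.16


def _base_preset(n_reads: int, seed: int) -> SimConfig:
    config = SimConfig(n_reads=n_reads, seed=seed, frag_rate=0.08)
    config.hotspots = [
        HotspotSpec(ref_id, coord, 1.0)
        for ref_id, coords in CANONICAL_HOTSPOTS.items()
        for coord in coords
    ]
    return config


def control_preset(n_reads: int = 50_000, seed: int = 0) -> SimConfig:
    """No-blocker control calibrated so the closed-form class fractions match
    the reference condition (rRNA 64%, tRNA 0.37% of mapped reads).

    With no blockers the capture probability of every transcript equals its
    poly-A baseline, so the baselines solve in closed form from the target
    fractions given the pool composition.
    """
    config = _base_preset(n_reads, seed)
    a = config.class_abundance
    f_r, f_t = CONTROL_FRACTIONS["rRNA"], CONTROL_FRACTIONS["tRNA"]
    f_m = 1.0 - f_r - f_t
    z = a["mRNA"] * 1.0 / f_m  # normalizer implied by polyA_mRNA = 1
    config.polyA_baseline = {
        "mRNA": 1.0,
        "rRNA": f_r * z / a["rRNA"],
        "tRNA": f_t * z / a["tRNA"],
    }
    return config


def embr_preset(
    n_reads: int = 50_000,
    seed: int = 0,
    with_hotspot_blockers: bool = False,
    target_rrna_fraction: float = EMBR_RRNA_FRACTION,
    blocker_len: int = 30,
    hotspot_offset: int = 100,
) -> SimConfig:
    """Blocked preset: 3'-end blockers on all three rRNAs (plus optional
    hotspot blockers ~100 nt downstream of each hotspot), with a common
    efficiency beta solved so the closed-form rRNA fraction equals
    ``target_rrna_fraction`` (default 16%).
    """
    config = control_preset(n_reads=n_reads, seed=seed)
    ref = build_reference(config)

    def blockers_with(beta: float) -> list[Blocker]:
        out = []
        for ref_id in RRNA_IDS:
            L = ref.length_of(ref_id)
            out.append(Blocker(ref_id, L - blocker_len + 1, L, beta))
        if with_hotspot_blockers:
            for h in config.hotspots:
                start = h.coordinate + hotspot_offset
                end = min(start + blocker_len - 1, ref.length_of(h.ref_id))
                out.append(Blocker(h.ref_id, start, end, beta))
        return out

    def objective(beta: float) -> float:
        config.blockers = blockers_with(beta)
        return expected_rrna_fraction(ref, config) - target_rrna_fraction

    lo, hi = objective(0.0), objective(1.0)
    if not (hi <= 0.0 <= lo):
        raise ValueError(
            f"target rRNA fraction {target_rrna_fraction} unreachable "
            f"(attainable range [{hi + target_rrna_fraction:.4f}, {lo + target_rrna_fraction:.4f}])"
        )
    beta = brentq(objective, 0.0, 1.0, xtol=1e-12)
    config.blockers = blockers_with(float(beta))
    return config
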