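"""Ungapped motif discovery by ZOOPS expectation-maximization, motif
scanning, and motif-pattern ("architecture") tabulation.

The site model is ZOOPS — zero or one occurrence per sequence: each
sequence either contains one motif occurrence (prior probability gamma,
uniform over eligible start positions) or none. Up to ``kmax`` motifs
are found sequentially, masking the occurrences of each found motif
before searching for the next. Motifs are ranked by information content
times expected site count, so motif 1 is the most conserved. Discovery
is deterministic: EM starts are seeded from the most frequent data
k-mers (ties broken lexicographically), independent of input order.

A protein's motif pattern is the ordered string of motif ids along the
sequence, e.g. "3-1-8-2"; pattern frequencies summarize a family's
architecture.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

AA = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AA)}
N_AA = len(AA)

DEFAULT_WMIN, DEFAULT_WMAX, DEFAULT_KMAX = 6, 10, 8
PSEUDOCOUNT = 0.01
N_STARTS = 20
MAX_ITER = 200
EM_TOL = 1e-6
MIN_GAMMA, MAX_GAMMA = 1e-3, 0.999


@dataclass
class MotifModel:
    id: int                 # rank; 1 = most conserved
    width: int
    pwm: np.ndarray         # (width, 20) position probabilities
    background: np.ndarray  # (20,) residue frequencies
    n_sites: float          # expected number of occurrences
    score: float            # information content x expected sites

    @property
    def consensus(self) -> str:
        return "".join(AA[i] for i in self.pwm.argmax(axis=1))

    def information_content(self) -> float:
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = self.pwm * np.log2(self.pwm / self.background)
        return float(np.nansum(terms))


@dataclass(frozen=True)
class MotifHit:
    protein_id: str
    motif_id: int
    start: int     # 1-based
    width: int
    score: float


@dataclass
class EMResult:
    pwm: np.ndarray
    gamma: float
    objective: list[float] = field(default_factory=list)
    posteriors: list[np.ndarray] = field(default_factory=list)  # per-seq site posteriors
    q_site: np.ndarray | None = None  # per-seq probability of having a site


def _encode(seqs: list[str]) -> list[np.ndarray]:
    out = []
    for s in seqs:
        try:
            out.append(np.array([AA_INDEX[a] for a in s.upper()], dtype=np.int64))
        except KeyError as e:
            raise ValueError(f"non-standard residue {e.args[0]!r} in sequence") from None
    return out


def _background(encoded: list[np.ndarray]) -> np.ndarray:
    counts = np.full(N_AA, 1.0)  # +1 smoothing
    for s in encoded:
        counts += np.bincount(s, minlength=N_AA)
    return counts / counts.sum()


def _window_scores(seq: np.ndarray, valid: np.ndarray, log_mat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-start sums of log_mat over windows; mask windows touching
    invalid (masked) positions. Returns (scores, usable boolean)."""
    w = log_mat.shape[0]
    m = len(seq) - w + 1
    if m <= 0:
        return np.empty(0), np.empty(0, dtype=bool)
    windows = np.lib.stride_tricks.sliding_window_view(seq, w)
    scores = log_mat[np.arange(w)[None, :], windows].sum(axis=1)
    ok = np.lib.stride_tricks.sliding_window_view(valid, w).all(axis=1)
    return scores, ok


class _BatchWindows:
    """Padded window tensors for one width over all sequences: residue
    indices (n, m_max, w) and a usable-window mask (n, m_max)."""

    def __init__(self, encoded: list[np.ndarray], valid: list[np.ndarray], w: int):
        self.w = w
        m_each = [max(len(s) - w + 1, 0) for s in encoded]
        self.m_max = max(m_each + [0])
        n = len(encoded)
        self.windows = np.zeros((n, self.m_max, w), dtype=np.int64)
        self.ok = np.zeros((n, self.m_max), dtype=bool)
        for i, (seq, ok_pos) in enumerate(zip(encoded, valid)):
            if m_each[i] == 0:
                continue
            win = np.lib.stride_tricks.sliding_window_view(seq, w)
            self.windows[i, : m_each[i]] = win
            self.ok[i, : m_each[i]] = np.lib.stride_tricks.sliding_window_view(
                ok_pos, w
            ).all(axis=1)
        self.m_count = self.ok.sum(axis=1)
        self._flat_idx = (
            self.windows + N_AA * np.arange(w)[None, None, :]
        ).ravel()


def zoops_em(
    encoded: list[np.ndarray],
    valid: list[np.ndarray],
    init_pwm: np.ndarray,
    background: np.ndarray,
    max_iter: int = MAX_ITER,
    tol: float = EM_TOL,
    pseudocount: float = PSEUDOCOUNT,
    _batch: "_BatchWindows | None" = None,
) -> EMResult:
    """Run ZOOPS EM from one PWM start; the objective trace is the
    observed-data log likelihood relative to the background model and is
    non-decreasing."""
    w = init_pwm.shape[0]
    batch = _batch if _batch is not None and _batch.w == w else _BatchWindows(
        encoded, valid, w
    )
    pwm = init_pwm.copy()
    gamma = 0.5
    log_bg = np.log(background)
    objective: list[float] = []
    n = len(encoded)
    z = np.zeros((n, batch.m_max))
    has_windows = batch.m_count > 0
    for _ in range(max_iter):
        log_ratio = np.log(pwm) - log_bg[None, :]
        scores = log_ratio[np.arange(w)[None, None, :], batch.windows].sum(axis=2)
        scores = np.where(batch.ok, scores, -np.inf)
        smax = np.where(has_windows, scores.max(axis=1, initial=-np.inf), 0.0)
        ex = np.exp(scores - smax[:, None], where=batch.ok, out=np.zeros_like(scores))
        sumex = ex.sum(axis=1)
        m_safe = np.maximum(batch.m_count, 1)
        denom = (1.0 - gamma) * np.exp(-smax) + (gamma / m_safe) * sumex
        z = (gamma / m_safe[:, None]) * ex / denom[:, None]
        z[~has_windows] = 0.0
        ll = float(
            np.sum(np.log(denom[has_windows]) + smax[has_windows])
            + (~has_windows).sum() * np.log(max(1.0 - gamma, 1e-300))
        )
        objective.append(ll)
        # M-step: weighted residue counts via one flat bincount
        flat_w = np.broadcast_to(z[:, :, None], batch.windows.shape).ravel()
        counts = np.bincount(
            batch._flat_idx, weights=flat_w, minlength=w * N_AA
        ).reshape(w, N_AA) + pseudocount
        pwm = counts / counts.sum(axis=1, keepdims=True)
        q_site = z.sum(axis=1)
        gamma = float(np.clip(q_site.mean(), MIN_GAMMA, MAX_GAMMA))
        if len(objective) >= 2 and objective[-1] - objective[-2] < tol:
            break
    q_site = z.sum(axis=1)
    posteriors = [
        z[i, batch.ok[i]] if batch.m_count[i] else np.zeros(0) for i in range(n)
    ]
    return EMResult(pwm=pwm, gamma=gamma, objective=objective,
                    posteriors=posteriors, q_site=q_site)


def _seed_kmers(seqs: list[str], valid: list[np.ndarray], w: int, n_starts: int) -> list[str]:
    """Most frequent unmasked k-mers of width w; ties lexicographic, so
    seeding depends on content, not input order."""
    counts: Counter[str] = Counter()
    for s, ok in zip(seqs, valid):
        seen = set()
        for j in range(len(s) - w + 1):
            if ok[j : j + w].all():
                seen.add(s[j : j + w].upper())
        counts.update(seen)  # per-sequence presence, ZOOPS-style
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return [k for k, _ in ranked[:n_starts]]


def _pwm_from_kmer(kmer: str, p_match: float = 0.6) -> np.ndarray:
    w = len(kmer)
    pwm = np.full((w, N_AA), (1.0 - p_match) / (N_AA - 1))
    for i, a in enumerate(kmer):
        pwm[i, AA_INDEX[a]] = p_match
    return pwm


def discover_motifs(
    sequences: list[str],
    wmin: int = DEFAULT_WMIN,
    wmax: int = DEFAULT_WMAX,
    kmax: int = DEFAULT_KMAX,
    seed: int = 0,
    n_starts: int = N_STARTS,
    max_iter: int = MAX_ITER,
) -> list[MotifModel]:
    """Sequential ZOOPS motif discovery.

    Finds up to ``kmax`` motifs of widths ``wmin..wmax``; after each
    motif, its confident occurrences (posterior site probability > 0.5)
    are masked. Returns motifs ranked by score (IC x expected sites).
    ``seed`` is accepted for interface stability; discovery is fully
    deterministic because starts are derived from data content.
    """
    del seed  # deterministic k-mer seeding; no randomness consumed
    if len(sequences) < 2:
        raise ValueError("motif discovery needs at least 2 sequences")
    if min(len(s) for s in sequences) < wmin:
        raise ValueError(f"all sequences must be at least {wmin} residues")
    encoded = _encode(sequences)
    background = _background(encoded)
    valid = [np.ones(len(s), dtype=bool) for s in encoded]

    found: list[MotifModel] = []
    for _ in range(kmax):
        best: tuple[float, int, str, EMResult] | None = None
        for w in range(wmin, min(wmax, min(len(s) for s in sequences)) + 1):
            batch = _BatchWindows(encoded, valid, w)
            for kmer in _seed_kmers(sequences, valid, w, n_starts):
                res = zoops_em(encoded, valid, _pwm_from_kmer(kmer), background,
                               max_iter=max_iter, _batch=batch)
                model = MotifModel(0, w, res.pwm, background,
                                   float(res.q_site.sum()), 0.0)
                score = model.information_content() * model.n_sites
                cand = (score, -w, kmer, res)
                if best is None or cand[:3] > best[:3]:
                    best = cand
        if best is None:
            break
        score, neg_w, _, res = best
        if res.q_site.sum() < 2.0:  # a motif must be supported by >1 sequence
            break
        model = MotifModel(len(found) + 1, -neg_w, res.pwm, background,
                           float(res.q_site.sum()), score)
        found.append(model)
        _mask_occurrences(encoded, valid, res, model.width)
    found.sort(key=lambda m: -m.score)
    for rank, m in enumerate(found, start=1):
        m.id = rank
    return found


def _mask_occurrences(encoded, valid, res: EMResult, w: int) -> None:
    for i, z in enumerate(res.posteriors):
        if res.q_site[i] <= 0.5 or len(z) == 0:
            continue
        usable = np.flatnonzero(
            np.lib.stride_tricks.sliding_window_view(valid[i], w).all(axis=1)
        )
        j = usable[int(z.argmax())]
        valid[i][j : j + w] = False


def scan_motifs(protein_id: str, aa_seq: str, motifs: list[MotifModel],
                score_threshold: float = 0.0) -> list[MotifHit]:
    """All non-overlapping motif occurrences with log-odds >= threshold.

    Candidate hits from every motif are resolved best-score-first with
    greedy non-overlap, then returned sorted by start position.
    """
    seq = _encode([aa_seq])[0]
    full = np.ones(len(seq), dtype=bool)
    candidates: list[MotifHit] = []
    for m in motifs:
        with np.errstate(divide="ignore"):
            log_odds = np.log2(m.pwm) - np.log2(m.background)[None, :]
        scores, ok = _window_scores(seq, full, log_odds)
        for j in np.flatnonzero(ok):
            if scores[j] >= score_threshold:
                candidates.append(
                    MotifHit(protein_id, m.id, int(j) + 1, m.width, float(scores[j]))
                )
    candidates.sort(key=lambda h: (-h.score, h.start, h.motif_id))
    taken = np.zeros(len(seq), dtype=bool)
    kept = []
    for h in candidates:
        span = slice(h.start - 1, h.start - 1 + h.width)
        if not taken[span].any():
            taken[span] = True
            kept.append(h)
    kept.sort(key=lambda h: h.start)
    return kept


def pattern_string(hits: list[MotifHit]) -> str:
    """Ordered motif-id pattern, N- to C-terminal, e.g. '3-1-8-2'."""
    ids = {h.protein_id for h in hits}
    if len(ids) > 1:
        raise ValueError(f"hits from multiple proteins: {sorted(ids)}")
    return "-".join(str(h.motif_id) for h in sorted(hits, key=lambda h: h.start))


def pattern_frequency(patterns: list[str]) -> pd.DataFrame:
    """Tabulate motif-pattern counts.

    ``percent`` is relative to proteins with a non-empty pattern;
    ``percent_all`` to all proteins.
    """
    total = len(patterns)
    nonempty = [p for p in patterns if p]
    counts = Counter(nonempty)
    rows = [
        {
            "pattern": p,
            "count": c,
            "percent": 100.0 * c / len(nonempty) if nonempty else 0.0,
            "percent_all": 100.0 * c / total if total else 0.0,
        }
        for p, c in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    return pd.DataFrame(rows, columns=["pattern", "count", "percent", "percent_all"])


def write_meme_minimal(motifs: list[MotifModel], path) -> None:
    """Write motifs as a MEME-minimal-format-compatible text block."""
    lines = ["MEME version 4", "", "ALPHABET= " + AA, ""]
    if motifs:
        bg = motifs[0].background
        lines += ["Background letter frequencies",
                  " ".join(f"{a} {f:.6f}" for a, f in zip(AA, bg)), ""]
    for m in motifs:
        lines.append(f"MOTIF motif_{m.id} {m.consensus}")
        lines.append(
            f"letter-probability matrix: alength= {N_AA} w= {m.width} "
            f"nsites= {m.n_sites:.1f}"
        )
        for row in m.pwm:
            lines.append(" " + " ".join(f"{p:.6f}" for p in row))
        lines.append("")
    with open(path, "w") as fh:
        fh.write("\n".join(lines))
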