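"""Multivariate Bernoulli-emission hidden Markov model over genomic bins.

The genome is tiled into fixed-size bins (500 bp by default); each
epigenomic/transcriptomic track is binarized per bin by a Poisson upper-tail
test against its genome-wide mean. A hidden Markov model with independent
Bernoulli emissions per track is then fitted by Baum-Welch (scaled
forward-backward, random restarts) and decoded by posterior argmax. The
"TSS-active" chromatin state — jointly enriched for CAGE, H3K4me3 and
H3K9ac emissions — is identified functionally, never by index, and is used
downstream to rescue weak tag clusters as low-confidence gene TSSs.

Each chromosome is treated as an independent observation chain.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.stats import poisson

REQUIRED_TSS_TRACKS = ("CAGE", "H3K4me3", "H3K9ac")


@dataclass
class BinnedTracks:
    """Binary bin x track matrices per chromosome, tiling each chrom."""

    bin_size: int
    track_names: list[str]
    chroms: list[str]
    matrices: dict[str, np.ndarray]  # chrom -> (n_bins, n_tracks) in {0,1}

    def __post_init__(self) -> None:
        for chrom, m in self.matrices.items():
            if not np.isin(m, (0, 1)).all():
                raise ValueError(f"non-binary entries on {chrom}")

    @property
    def n_tracks(self) -> int:
        return len(self.track_names)

    def chains(self) -> list[np.ndarray]:
        return [self.matrices[c] for c in self.chroms]

    def total_bins(self) -> int:
        return sum(m.shape[0] for m in self.matrices.values())


def binarize(
    counts: dict[str, np.ndarray],
    track_names: list[str],
    bin_size: int = 500,
    p_threshold: float = 1e-4,
) -> BinnedTracks:
    """Binarize per-bin counts with a Poisson upper-tail test.

    A bin is marked 1 when P(X >= count) under a Poisson with the track-wide
    mean is below ``p_threshold``. An all-zero track stays all-zero with a
    warning.
    """
    chroms = sorted(counts)
    stacked = np.vstack([counts[c] for c in chroms]).astype(float)
    if stacked.shape[1] != len(track_names):
        raise ValueError("track count mismatch between matrix and names")
    if (stacked < 0).any():
        raise ValueError("counts must be non-negative")
    out = {}
    means = stacked.mean(axis=0)
    binary_cols = []
    for j, name in enumerate(track_names):
        lam = means[j]
        if lam == 0:
            warnings.warn(f"track {name!r} is all-zero; emitted all-zero")
            binary_cols.append(np.zeros(stacked.shape[0], dtype=np.int8))
            continue
        col = stacked[:, j]
        # P(X >= c) = sf(c - 1)
        tail = poisson.sf(col - 1, lam)
        binary_cols.append((tail < p_threshold).astype(np.int8))
    binary = np.column_stack(binary_cols)
    offset = 0
    for c in chroms:
        n = counts[c].shape[0]
        out[c] = binary[offset:offset + n]
        offset += n
    return BinnedTracks(bin_size, list(track_names), chroms, out)


@dataclass
class ChromatinHMM:
    """HMM parameters: initial pi, transitions T, Bernoulli emissions E."""

    initial: np.ndarray          # (n_states,)
    transitions: np.ndarray      # (n_states, n_states), row-stochastic
    emissions: np.ndarray        # (n_states, n_tracks), P(track=1 | state)
    track_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if abs(self.initial.sum() - 1.0) > 1e-9:
            raise ValueError("initial distribution does not sum to 1")
        if np.abs(self.transitions.sum(axis=1) - 1.0).max() > 1e-9:
            raise ValueError("transition rows must sum to 1")
        if ((self.emissions < 0) | (self.emissions > 1)).any():
            raise ValueError("emission probabilities must lie in [0,1]")

    @property
    def n_states(self) -> int:
        return self.initial.shape[0]

    def save(self, path: str | Path) -> None:
        payload = {
            "initial": self.initial.tolist(),
            "transitions": self.transitions.tolist(),
            "emissions": self.emissions.tolist(),
            "track_names": self.track_names,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "ChromatinHMM":
        d = json.loads(Path(path).read_text())
        return cls(
            np.array(d["initial"]), np.array(d["transitions"]),
            np.array(d["emissions"]), list(d["track_names"]),
        )


def _emission_probs(model: ChromatinHMM, chain: np.ndarray) -> np.ndarray:
    """b[t, s] = prod_j E[s,j]^x ... (1-E)^(1-x), vectorized."""
    e = np.clip(model.emissions, 0.0, 1.0)
    x = chain.astype(float)
    # log-free product via matmul on log is unstable at exact 0/1; do direct.
    b = np.ones((chain.shape[0], model.n_states))
    for j in range(e.shape[1]):
        pj = e[:, j][None, :]
        xj = x[:, j][:, None]
        b *= np.where(xj > 0.5, pj, 1.0 - pj)
    return b


def _forward_backward(model: ChromatinHMM, chain: np.ndarray):
    """Scaled forward-backward. Returns (loglik, gamma, xi_sum, scale_ok)."""
    b = _emission_probs(model, chain)
    n, S = b.shape[0], model.n_states
    alpha = np.zeros((n, S))
    beta = np.zeros((n, S))
    scale = np.zeros(n)
    a = model.initial * b[0]
    scale[0] = a.sum()
    if scale[0] == 0:
        return -np.inf, None, None, False
    alpha[0] = a / scale[0]
    T = model.transitions
    for t in range(1, n):
        a = (alpha[t - 1] @ T) * b[t]
        scale[t] = a.sum()
        if scale[t] == 0:
            return -np.inf, None, None, False
        alpha[t] = a / scale[t]
    beta[n - 1] = 1.0
    for t in range(n - 2, -1, -1):
        beta[t] = (T @ (b[t + 1] * beta[t + 1])) / scale[t + 1]
    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    xi_sum = np.zeros((S, S))
    for t in range(n - 1):
        xi = (alpha[t][:, None] * T) * (b[t + 1] * beta[t + 1])[None, :] / scale[t + 1]
        xi_sum += xi
    return float(np.log(scale).sum()), gamma, xi_sum, True


def loglik(model: ChromatinHMM, tracks: BinnedTracks) -> float:
    """Total log-likelihood over all chains (-inf if any chain impossible)."""
    if tracks.track_names != model.track_names:
        raise ValueError("track-name mismatch between model and data")
    total = 0.0
    for chain in tracks.chains():
        ll, *_ = _forward_backward(model, chain)
        if ll == -np.inf:
            return -np.inf
        total += ll
    return total


def fit(
    tracks: BinnedTracks,
    n_states: int = 15,
    seed: int = 0,
    n_restarts: int = 5,
    max_iter: int = 100,
    tol: float = 1e-4,
) -> tuple[ChromatinHMM, float]:
    """Baum-Welch fit with random restarts; best log-likelihood wins.

    The per-iteration log-likelihood is checked to be non-decreasing within
    1e-8; parameters stay row-stochastic/valid throughout. Fully reproducible
    given ``seed`` (restart sub-seeds are derived from it); restart ties are
    broken by restart index.
    """
    if n_states < 2:
        raise ValueError("n_states must be >= 2")
    if tracks.total_bins() < 10 * n_states:
        raise ValueError("need at least 10 bins per state")
    chains = tracks.chains()
    if np.unique(np.vstack(chains), axis=0).shape[0] == 1:
        warnings.warn("all bins identical; fit is degenerate")
    master = np.random.default_rng(seed)
    sub_seeds = master.integers(0, 2**31 - 1, size=n_restarts)
    best: tuple[float, int, ChromatinHMM] | None = None
    for r, s in enumerate(sub_seeds):
        model, ll = _fit_once(chains, tracks.track_names, n_states, int(s),
                              max_iter, tol)
        if best is None or ll > best[0]:
            best = (ll, r, model)
    assert best is not None
    model = _consolidate_duplicates(best[2], chains)
    return model, loglik(model, tracks)


def _consolidate_duplicates(model: ChromatinHMM, chains,
                            tol: float = 0.05) -> ChromatinHMM:
    """Merge states whose emission vectors are numerically indistinguishable.

    With more states than distinct signal combinations, EM freely clones a
    pattern state into interchangeable copies that split its occupancy;
    merging them (occupancy-weighted) restores one state per combination
    without changing the modeled distribution materially.
    """
    S = model.n_states
    occ = np.zeros(S)
    for chain in chains:
        _, gamma, _, ok = _forward_backward(model, chain)
        if ok:
            occ += gamma.sum(axis=0)
    parent = list(range(S))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(S):
        for j in range(i + 1, S):
            if np.abs(model.emissions[i] - model.emissions[j]).max() < tol:
                parent[max(find(i), find(j))] = min(find(i), find(j))
    groups: dict[int, list[int]] = {}
    for i in range(S):
        groups.setdefault(find(i), []).append(i)
    if len(groups) == S:
        return model
    roots = sorted(groups)
    w = np.maximum(occ, 1e-12)
    G = len(roots)
    initial = np.zeros(G)
    emissions = np.zeros((G, model.emissions.shape[1]))
    trans = np.zeros((G, G))
    for a, ra in enumerate(roots):
        members = groups[ra]
        wa = w[members]
        initial[a] = model.initial[members].sum()
        emissions[a] = (wa[:, None] * model.emissions[members]).sum(0) / wa.sum()
        for b, rb in enumerate(roots):
            cols = model.transitions[np.ix_(members, groups[rb])].sum(axis=1)
            trans[a, b] = (wa * cols).sum() / wa.sum()
    initial /= initial.sum()
    trans /= trans.sum(axis=1, keepdims=True)
    return ChromatinHMM(initial, trans, emissions, list(model.track_names))


def _fit_once(chains, track_names, n_states, seed, max_iter, tol):
    rng = np.random.default_rng(seed)
    n_tracks = chains[0].shape[1]
    # Init: one state per well-supported distinct emission pattern (most
    # frequent first) so each recurrent signal combination claims exactly one
    # state. Surplus states start as exact uniform clones: their EM updates
    # stay identical by symmetry, so they cannot split a pattern's mass.
    # Transitions sticky-uniform.
    stacked = np.vstack(chains)
    patterns, counts = np.unique(stacked, axis=0, return_counts=True)
    min_support = max(10, int(0.002 * stacked.shape[0]))
    keep = counts >= min_support
    if not keep.any():
        keep = counts >= 1
    order = np.argsort(-counts[keep], kind="stable")
    seeds = patterns[keep][order[:n_states]].astype(float)
    k = seeds.shape[0]
    emissions = np.full((n_states, n_tracks), 0.5)
    emissions[:k] = np.clip(
        0.85 * seeds + 0.15 * rng.uniform(0.2, 0.8, (k, n_tracks)), 0.01, 0.99
    )
    transitions = np.full((n_states, n_states), 0.1 / max(n_states - 1, 1))
    np.fill_diagonal(transitions, 0.9)
    initial = np.full(n_states, 1.0 / n_states)
    model = ChromatinHMM(initial, transitions, emissions, list(track_names))

    prev_ll = -np.inf
    for iteration in range(max_iter):
        total_ll = 0.0
        init_acc = np.zeros(n_states)
        xi_acc = np.zeros((n_states, n_states))
        gamma_acc = np.zeros(n_states)
        gx_acc = np.zeros((n_states, n_tracks))
        for chain in chains:
            ll, gamma, xi_sum, ok = _forward_backward(model, chain)
            if not ok:
                raise RuntimeError("zero-probability observation during EM")
            total_ll += ll
            init_acc += gamma[0]
            xi_acc += xi_sum
            gamma_acc += gamma.sum(axis=0)
            gx_acc += gamma.T @ chain
        if total_ll < prev_ll - 1e-8:
            raise AssertionError(
                f"Baum-Welch log-likelihood decreased: {prev_ll} -> {total_ll}"
            )
        improved = total_ll - prev_ll
        prev_ll = total_ll
        # M-step
        initial = init_acc / init_acc.sum()
        row = xi_acc.sum(axis=1, keepdims=True)
        transitions = np.where(row > 0, xi_acc / np.where(row > 0, row, 1.0),
                               1.0 / n_states)
        transitions /= transitions.sum(axis=1, keepdims=True)
        emissions = gx_acc / np.where(gamma_acc[:, None] > 0, gamma_acc[:, None], 1.0)
        emissions = np.clip(emissions, 1e-6, 1 - 1e-6)
        model = ChromatinHMM(initial, transitions, emissions, list(track_names))
        if 0 <= improved < tol and iteration > 0:
            break
    return model, prev_ll


def posterior(model: ChromatinHMM, chain: np.ndarray) -> np.ndarray:
    ll, gamma, _, ok = _forward_backward(model, chain)
    if not ok:
        raise ValueError("observation sequence impossible under model")
    return gamma


def decode(model: ChromatinHMM, tracks: BinnedTracks, method: str = "posterior"
           ) -> dict[str, np.ndarray]:
    """Per-bin state labels per chrom.

    Default is posterior (forward-backward) argmax with ties broken toward
    the lower state index; Viterbi is available via ``method='viterbi'``.
    """
    if tracks.track_names != model.track_names:
        raise ValueError("track-name mismatch between model and data")
    out = {}
    for chrom in tracks.chroms:
        chain = tracks.matrices[chrom]
        if method == "posterior":
            out[chrom] = np.argmax(posterior(model, chain), axis=1)
        elif method == "viterbi":
            out[chrom] = _viterbi(model, chain)
        else:
            raise ValueError(f"unknown decode method {method!r}")
    return out


def _viterbi(model: ChromatinHMM, chain: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        logb = np.log(_emission_probs(model, chain))
        logT = np.log(model.transitions)
        logpi = np.log(model.initial)
    n, S = logb.shape
    delta = logpi + logb[0]
    back = np.zeros((n, S), dtype=int)
    for t in range(1, n):
        cand = delta[:, None] + logT
        back[t] = np.argmax(cand, axis=0)
        delta = cand[back[t], np.arange(S)] + logb[t]
    path = np.zeros(n, dtype=int)
    path[-1] = int(np.argmax(delta))
    for t in range(n - 2, -1, -1):
        path[t] = back[t + 1][path[t + 1]]
    return path


def tss_active_state(model: ChromatinHMM) -> int:
    """Index of the state jointly enriched for CAGE, H3K4me3 and H3K9ac.

    Scored as the product of the three emission probabilities; ties break
    toward the lower state index. State indices are arbitrary labels, so the
    TSS-active state is always identified functionally like this.
    """
    missing = [t for t in REQUIRED_TSS_TRACKS if t not in model.track_names]
    if missing:
        raise ValueError(f"model lacks required tracks {missing}")
    cols = [model.track_names.index(t) for t in REQUIRED_TSS_TRACKS]
    score = np.prod(model.emissions[:, cols], axis=1)
    return int(np.argmax(score))
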