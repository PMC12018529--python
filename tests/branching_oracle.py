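"""Independent Monte-Carlo oracle for the three-type branching processes.

Simulates the second-epidemic branching process directly from its
generative description -- no PGFs, no fixed points -- so the extinction
frequencies it produces are an independent check of the analytic
extinction probabilities.

Generative model for the offspring of a non-root individual of a given
type (1 = prior case with a red path of descent, 2 = prior case without,
3 = escaped the first epidemic):

1. the individual has K ~ (size-biased degree minus 1) tree-children;
2. each child independently carries label A (has a red path of descent)
   with probability 1 - q_tilde, and its edge is red with probability p;
3. the parent's own label constrains the configuration (rejection step):
   a label-A parent (type 1) must have at least one A-child on a red
   edge, a label-B parent (types 2, 3) must have none;
4. child types: A-children are type 1; B-children of a red parent are
   type 2 on a red edge and type 3 otherwise; B-children of a blue
   parent are all type 3;
5. second-epidemic thinning keeps each child independently:
   forward process with probability pi[a(parent), a(child)], backward
   (susceptibility-set) process with the transposed probability, and
   backward-polarized with the once-for-all coin: a red parent has no
   offspring at all with probability 1 - alpha, otherwise (and for blue
   parents always) each child is kept with probability p'.

Runs are advanced generation-synchronously in flat numpy arrays; a run
whose alive population reaches ``cap`` is declared surviving (for a
supercritical process the probability of extinction from ``cap``
individuals is at most max(xi)^cap, negligible here).
"""

from __future__ import annotations

import numpy as np


def size_biased_sampler(dist, tail_tol: float = 1e-13):
    """Inverse-CDF sampler for the size-biased degree D-tilde, built from
    the pmf alone (independent of the PGF machinery under test)."""
    ks, probs = [], []
    acc = 0.0
    for k in range(1, 100_000):
        pk = dist.size_biased_pmf(k)
        if pk > 0:
            ks.append(k)
            probs.append(pk)
            acc += pk
        if acc > 1.0 - tail_tol:
            break
    ks = np.array(ks)
    cdf = np.cumsum(probs)
    cdf[-1] = max(cdf[-1], 1.0)

    def draw(n, rng):
        return ks[np.searchsorted(cdf, rng.random(n), side="right")]

    return draw


def _sample_children(types, sb_draw, p, q_tilde, rng):
    """Offspring labels for a batch of parents, honouring the rejection
    constraint of step 3.  Returns (child_parent_index, child_types)."""
    n = len(types)
    out_parent = []
    out_types = []
    pending = np.arange(n)
    pend_A = types == 1
    pend_red = types != 3
    while len(pending):
        k = sb_draw(len(pending), rng) - 1  # size-biased degree minus 1
        k = np.maximum(k, 0)
        total = int(k.sum())
        seg = np.repeat(np.arange(len(pending)), k)
        child_A = rng.random(total) < (1.0 - q_tilde)
        edge_red = rng.random(total) < p
        a_red = child_A & edge_red
        has_a_red = np.zeros(len(pending), dtype=bool)
        np.logical_or.at(has_a_red, seg, a_red)
        ok = np.where(pend_A, has_a_red, ~has_a_red)
        keep_children = ok[seg]
        seg_k = seg[keep_children]
        cA = child_A[keep_children]
        eR = edge_red[keep_children]
        pr = pend_red[seg_k]
        ctype = np.where(cA, 1, np.where(pr & eR, 2, 3))
        out_parent.append(pending[seg_k])
        out_types.append(ctype)
        pending = pending[~ok]
        pend_A = pend_A[~ok]
        pend_red = pend_red[~ok]
    if not out_parent:
        return np.array([], dtype=int), np.array([], dtype=int)
    return np.concatenate(out_parent), np.concatenate(out_types)


def _thin(parent_types, child_types, im, mode, rng):
    """Second-epidemic thinning: which tree-children become offspring."""
    a_par = (parent_types != 3).astype(int)
    a_chi = (child_types != 3).astype(int)
    pimat = im.pi_matrix
    if mode == "forward":
        probs = pimat[a_par, a_chi]
    elif mode == "backward":
        probs = pimat[a_chi, a_par]
    elif mode == "backward_polarized":
        probs = np.full(len(child_types), im.p_prime)
    else:
        raise ValueError(mode)
    return rng.random(len(child_types)) < probs


def _simulate_batch(sb_draw, p, q_tilde, im, start_type, mode, b, cap, rng):
    run_id = np.arange(b)
    types = np.full(b, start_type)
    active = np.ones(b, dtype=bool)
    extinct = np.zeros(b, dtype=bool)
    for _ in range(10_000):
        parents = np.bincount(run_id, minlength=b)
        if mode == "backward_polarized" and len(types):
            red = types != 3
            fertile = ~red | (rng.random(len(types)) < im.alpha)
            run_id, types = run_id[fertile], types[fertile]
        if len(types):
            cp, ct = _sample_children(types, sb_draw, p, q_tilde, rng)
            if len(cp):
                keep = _thin(types[cp], ct, im, mode, rng)
                child_runs = run_id[cp][keep]
                child_types = ct[keep]
            else:
                child_runs = np.array([], dtype=int)
                child_types = np.array([], dtype=int)
        else:
            child_runs = np.array([], dtype=int)
            child_types = np.array([], dtype=int)
        counts = np.bincount(child_runs, minlength=b)
        newly_extinct = active & (parents > 0) & (counts == 0)
        extinct |= newly_extinct
        survived = active & (counts >= cap)
        active &= ~(newly_extinct | survived)
        if not active.any():
            break
        still = active[child_runs]
        run_id, types = child_runs[still], child_types[still]
    else:  # pragma: no cover
        raise RuntimeError("branching oracle exceeded generation limit")
    return int(extinct.sum())


def simulate_extinction(
    dist,
    p,
    q_tilde,
    im,
    start_type: int,
    mode: str = "forward",
    runs: int = 100_000,
    cap: int = 50,
    seed: int = 0,
    batch: int = 20_000,
) -> float:
    """Fraction of ``runs`` in which the process dies out, starting from a
    single non-root individual of ``start_type``."""
    rng = np.random.default_rng(seed)
    sb_draw = size_biased_sampler(dist)
    extinct = 0
    done = 0
    while done < runs:
        b = min(batch, runs - done)
        extinct += _simulate_batch(sb_draw, p, q_tilde, im, start_type, mode, b, cap, rng)
        done += b
    return extinct / runs
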