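"""Layer-wise relevance propagation (z-rule) and the relevance metric suite.

Relevance starts at the predicted output unit's pre-softmax score and is
redistributed backwards through the fully connected stack with the z-rule:
the message from upper-layer neuron j to lower-layer neuron i is

    R_{i<-j} = (z_ij / z_j) * R_j,      z_ij = u_i * w_ij,
    z_j = sum_i z_ij + b_j,

summed over j to give each neuron's relevance.  For a single linear layer
this reduces to R_{i<-j} = z_ij exactly, and for bias-free networks the total
relevance is conserved layer to layer (with biases, each layer absorbs the
fraction b_j / z_j).  A stabilizer replaces z_j by z_j + eps*sign(z_j) with
eps relative to the layer scale, so zero denominators never occur.

The metric suite mirrors the downstream reporting: mean absolute relevance
over correctly classified trials, normalized to its maximum; smoothing of each
100-point trajectory block with three passes of a (0.25, 0.50, 0.25) kernel
(edge weight folded into the centre so block totals are preserved); min-max
rescaling to [0, 1]; a top-100 mask; and per-trajectory / per-joint summed
contributions in percent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dnn import TrainedNetwork
from .exceptions import ConfigurationError, SignalError
from .signal_prep import TRAJECTORIES, N_PHASE_POINTS

SMOOTH_KERNEL = (0.25, 0.50, 0.25)


def _stabilized(z: np.ndarray, eps_rel: float) -> np.ndarray:
    scale = np.max(np.abs(z))
    eps = eps_rel * (scale if scale > 0 else 1.0)
    return z + eps * np.where(z >= 0, 1.0, -1.0)


def propagate(net: TrainedNetwork, x: np.ndarray, target: int | None = None,
              eps_rel: float = 1e-9, bias_mode: str = "absorb",
              return_layers: bool = False):
    """Per-input relevance (one value per input feature) for a single row.

    ``target`` selects the output unit whose pre-softmax score is decomposed;
    by default the predicted class.  ``bias_mode`` is "absorb" (bias relevance
    dropped, the printed rule) or "redistribute" (the absorbed share split
    equally over the layer's inputs).  With ``return_layers`` the relevance
    vector of every layer (output first, input last) is returned as well, so
    layer-wise conservation can be audited.
    """
    if bias_mode not in ("absorb", "redistribute"):
        raise ConfigurationError("bias_mode must be 'absorb' or 'redistribute'")
    x = np.asarray(x, dtype=float).ravel()
    scores, cache = net.forward(x, cache=True)
    scores = scores[0]
    if target is None:
        target = int(np.argmax(scores))
    if not 0 <= target < net.config.n_outputs:
        raise ConfigurationError(f"target unit {target} out of range")

    # relevance at the output layer: the chosen unit's pre-activation score
    R = np.zeros(net.config.n_outputs)
    R[target] = cache.pre_activations[-1][0, target]
    layers = [R.copy()]
    for l in range(len(net.weights) - 1, -1, -1):
        u_prev = cache.activations[l][0]       # inputs to layer l
        w = net.weights[l]
        zij = u_prev[:, None] * w              # local pre-activations
        zj = zij.sum(axis=0) + net.biases[l]   # global pre-activations
        zj_s = _stabilized(zj, eps_rel)
        R_prev = zij @ (R / zj_s)
        if bias_mode == "redistribute":
            absorbed = (net.biases[l] / zj_s) * R
            R_prev = R_prev + absorbed.sum() / len(u_prev)
        R = R_prev
        layers.append(R.copy())
    if return_layers:
        return R, layers
    return R


def relevance_batch(net: TrainedNetwork, X: np.ndarray,
                    targets: np.ndarray | None = None,
                    eps_rel: float = 1e-9, bias_mode: str = "absorb") -> np.ndarray:
    """Row-wise :func:`propagate` over a matrix; returns (rows, n_inputs)."""
    X = np.atleast_2d(X)
    if targets is None:
        targets = net.predict(X)
    return np.vstack([
        propagate(net, X[i], int(targets[i]), eps_rel, bias_mode)
        for i in range(X.shape[0])
    ])


def aggregate(maps: np.ndarray, correct_mask: np.ndarray) -> np.ndarray:
    """Mean absolute relevance over correctly classified trials, normalized to
    its maximum.  Raises when no trial is correctly classified."""
    maps = np.atleast_2d(maps)
    correct_mask = np.asarray(correct_mask, dtype=bool)
    if maps.shape[0] != correct_mask.shape[0]:
        raise ConfigurationError("mask length must match the number of relevance maps")
    if not correct_mask.any():
        raise SignalError("no correctly classified trials to aggregate")
    agg = np.mean(np.abs(maps[correct_mask]), axis=0)
    peak = agg.max()
    if peak == 0:
        raise SignalError("aggregated relevance is identically zero")
    return agg / peak


def smooth(v: np.ndarray, block_size: int = N_PHASE_POINTS, passes: int = 3) -> np.ndarray:
    """Three passes of the (0.25, 0.50, 0.25) kernel within each block.

    Blocks are smoothed independently (no bleed between trajectories); at
    block edges the missing neighbour's weight folds into the centre, so each
    pass preserves the block total exactly and leaves constant blocks
    untouched.
    """
    v = np.asarray(v, dtype=float)
    if v.ndim != 1 or v.size % block_size:
        raise ConfigurationError(f"vector length {v.size} is not a multiple of {block_size}")
    out = v.copy()
    wl, wc, wr = SMOOTH_KERNEL
    for _ in range(passes):
        nxt = np.empty_like(out)
        for b in range(v.size // block_size):
            blk = out[b * block_size:(b + 1) * block_size]
            res = wc * blk
            res[1:] += wl * blk[:-1]
            res[:-1] += wr * blk[1:]
            res[0] += wl * blk[0]    # fold the missing left neighbour's weight
            res[-1] += wr * blk[-1]  # fold the missing right neighbour's weight
            nxt[b * block_size:(b + 1) * block_size] = res
        out = nxt
    return out


def rescale_and_rank(v: np.ndarray, k: int = 100) -> tuple[np.ndarray, np.ndarray]:
    """Min-max rescale to [0, 1] (max exactly 1) and mask of the k largest
    values, ties broken toward the lower variable index."""
    v = np.asarray(v, dtype=float)
    if not np.any(v):
        raise SignalError("cannot rescale an all-zero vector")
    lo, hi = v.min(), v.max()
    if hi == lo:
        raise SignalError("cannot rescale a constant vector")
    rescaled = (v - lo) / (hi - lo)
    if not 0 < k <= v.size:
        raise ConfigurationError(f"k={k} outside [1, {v.size}]")
    order = np.argsort(-rescaled, kind="stable")  # stable: lower index wins ties
    mask = np.zeros(v.size, dtype=bool)
    mask[order[:k]] = True
    return rescaled, mask


def trajectory_contributions(v: np.ndarray,
                             block_size: int = N_PHASE_POINTS
                             ) -> tuple[dict[str, float], dict[str, float]]:
    """Per-trajectory and per-joint summed contributions in percent.

    The six trajectory percentages (wrist/elbow/shoulder angle, then moment)
    sum to 100; joint totals add each joint's angle and moment shares.
    """
    v = np.asarray(v, dtype=float)
    if v.size != len(TRAJECTORIES) * block_size:
        raise ConfigurationError(
            f"expected a {len(TRAJECTORIES) * block_size}-vector, got {v.size}")
    if np.any(v < 0):
        raise ConfigurationError("contributions require a non-negative vector")
    total = v.sum()
    if total == 0:
        raise SignalError("cannot compute contributions of a zero vector")
    sums = v.reshape(len(TRAJECTORIES), block_size).sum(axis=1)
    pct = {name: float(100.0 * s / total) for name, s in zip(TRAJECTORIES, sums)}
    joints = {
        joint: pct[f"{joint}_angle"] + pct[f"{joint}_moment"]
        for joint in ("wrist", "elbow", "shoulder")
    }
    return pct, joints


@dataclass
class RelevanceMap:
    """All stages of the relevance pipeline for one height-pair model."""

    pair_id: str
    per_trial: np.ndarray          # (n_trials, 600) raw relevance
    correct_mask: np.ndarray
    aggregated: np.ndarray         # mean |R| over correct trials, max-normalized
    smoothed: np.ndarray
    rescaled: np.ndarray           # min-max to [0, 1]
    top_mask: np.ndarray           # exactly k True entries
    trajectory_pct: dict[str, float]
    joint_pct: dict[str, float]

    def summary(self) -> dict:
        return {
            "pair_id": self.pair_id,
            "n_trials": int(self.per_trial.shape[0]),
            "n_correct": int(self.correct_mask.sum()),
            "trajectory_pct": self.trajectory_pct,
            "joint_pct": self.joint_pct,
            "top_variables": np.nonzero(self.top_mask)[0].tolist(),
        }


def relevance_analysis(net: TrainedNetwork, X: np.ndarray, y: np.ndarray,
                       pair_id: str = "", k: int = 100,
                       eps_rel: float = 1e-9, bias_mode: str = "absorb") -> RelevanceMap:
    """End-to-end relevance pipeline for one trained pair classifier.

    Propagates every row's predicted-class score, keeps correctly classified
    rows, aggregates, smooths, rescales, ranks the top-``k`` variables, and
    sums contributions per trajectory; contributions and the ranking both use
    the smoothed-rescaled scores.
    """
    pred = net.predict(X)
    correct = pred == np.asarray(y).astype(int)
    maps = relevance_batch(net, X, targets=pred, eps_rel=eps_rel, bias_mode=bias_mode)
    agg = aggregate(maps, correct)
    sm = smooth(agg)
    rescaled, mask = rescale_and_rank(sm, k=k)
    pct, joints = trajectory_contributions(rescaled)
    return RelevanceMap(pair_id=pair_id, per_trial=maps, correct_mask=correct,
                        aggregated=agg, smoothed=sm, rescaled=rescaled,
                        top_mask=mask, trajectory_pct=pct, joint_pct=joints)
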