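"""Aortic landmark detection.

Three providers share one output type (a named point set in mm):

* multi-scale reinforcement-learning agents: per-resolution Q-networks that
  navigate the volume from random start positions toward the target landmark,
  run coarse to fine (16 -> 8 -> 4 -> 2 mm by default);
* a ground-truth passthrough (phantom oracle), so downstream geometry and
  diametry never depend on agent convergence;
* a mask-topology fallback that derives the five landmarks from the
  segmentation alone (geodesic endpoints + curvature of the medial path).

The agent design: state is the normalized intensity patch (9^3 voxels)
centred on the agent; actions are the six unit-voxel axis moves; the reward
per step is the decrease in Euclidean distance to the target (mm) with a
terminal bonus when the agent lands within one voxel. Training is standard
Q-learning with an experience replay buffer, an epsilon-greedy schedule and a
periodically synced target network — all seeded and deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .errors import InputError
from .nnet import MLP, Adam
from .phantom import GroundTruth, LANDMARK_NAMES
from .volume import Volume, resample_isotropic

__all__ = ["AgentConfig", "LandmarkAgents", "train_landmark_agents",
           "detect_landmarks", "landmark_error", "geometric_median",
           "oracle_landmarks", "LANDMARK_NAMES"]

_ACTIONS = np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0],
                     [0, -1, 0], [0, 0, 1], [0, 0, -1]])


@dataclass
class AgentConfig:
    """Hyperparameters for one landmark's multi-resolution agents."""

    resolutions_mm: tuple = (16.0, 8.0, 4.0, 2.0)
    patch_size: int = 9
    max_steps: int = 60
    episodes: int = 300
    epsilon_start: float = 1.0
    epsilon_end: float = 0.1
    replay_capacity: int = 10_000
    batch_size: int = 32
    discount: float = 0.9
    learning_rate: float = 1e-3
    hidden: tuple = (64, 64)
    target_sync: int = 250
    terminal_bonus_voxels: float = 1.0
    #: training starts for the non-coarsest agents are drawn within this many
    #: voxels of the target — at run time they take over from the coarser
    #: agent's estimate, so only the local policy matters
    fine_start_offset_voxels: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        res = tuple(float(r) for r in self.resolutions_mm)
        if len(res) < 1 or any(later >= earlier for later, earlier in zip(res[1:], res[:-1])):
            raise InputError("resolutions must be strictly descending")
        if self.episodes < 1:
            raise InputError("episodes must be >= 1")
        self.resolutions_mm = res


def _normalize(hu: np.ndarray) -> np.ndarray:
    return np.clip((hu + 100.0) / 500.0, 0.0, 1.0).astype(np.float32)


def _patch_at(x: np.ndarray, pos: np.ndarray, half: int) -> np.ndarray:
    """Edge-padded cube of side 2*half+1 centred at integer position."""
    lo = pos - half
    hi = pos + half + 1
    pad_lo = np.maximum(0, -lo)
    pad_hi = np.maximum(0, hi - np.asarray(x.shape))
    sl = tuple(slice(int(max(0, a)), int(min(n, b)))
               for a, b, n in zip(lo, hi, x.shape))
    core = x[sl]
    if pad_lo.any() or pad_hi.any():
        core = np.pad(core, list(zip(pad_lo.astype(int), pad_hi.astype(int))), mode="edge")
    return core


class _Env:
    """One resampled case: positions in voxel units, distances in mm."""

    def __init__(self, norm_vox: np.ndarray, target_vox: np.ndarray, res_mm: float):
        self.x = norm_vox
        self.target = target_vox
        self.res = res_mm
        self.shape = np.asarray(norm_vox.shape)

    def state(self, pos: np.ndarray, half: int) -> np.ndarray:
        return _patch_at(self.x, pos, half).ravel().astype(np.float64)

    def dist_mm(self, pos: np.ndarray) -> float:
        return float(np.linalg.norm((pos - self.target) * self.res))


@dataclass
class LandmarkAgents:
    """Trained per-resolution Q-networks for one landmark."""

    landmark_id: str
    cfg: AgentConfig
    nets: dict[float, MLP]
    training_log: dict[float, list[float]] = field(default_factory=dict)

    def save(self, path: str | Path) -> None:
        arrays = {}
        for res, net in self.nets.items():
            for k, v in net.state_arrays().items():
                arrays[f"r{res:g}_{k}"] = v
        meta = {"landmark_id": self.landmark_id, "cfg": asdict(self.cfg),
                "training_log": {str(k): v for k, v in self.training_log.items()}}
        np.savez(Path(path), __meta__=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "LandmarkAgents":
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["__meta__"]))
            cfg = AgentConfig(**{**meta["cfg"],
                                 "resolutions_mm": tuple(meta["cfg"]["resolutions_mm"]),
                                 "hidden": tuple(meta["cfg"]["hidden"])})
            nets = {}
            for res in cfg.resolutions_mm:
                net = _make_net(cfg)
                net.load_state_arrays({k[len(f"r{res:g}_"):]: data[k]
                                       for k in data.files
                                       if k.startswith(f"r{res:g}_")})
                nets[res] = net
        return cls(meta["landmark_id"], cfg, nets,
                   {float(k): v for k, v in meta["training_log"].items()})


def _make_net(cfg: AgentConfig, seed_offset: int = 0) -> MLP:
    sizes = [cfg.patch_size ** 3, *cfg.hidden, 6]
    return MLP(sizes, seed=cfg.seed + seed_offset)


def train_landmark_agents(cases: list[tuple[Volume, GroundTruth]],
                          landmark_id: str,
                          cfg: AgentConfig | None = None) -> LandmarkAgents:
    """Train one Q-network per resolution for a single named landmark."""
    cfg = cfg or AgentConfig()
    for _, gt in cases:
        if landmark_id not in gt.landmarks:
            raise InputError(f"case missing landmark {landmark_id!r}")

    nets: dict[float, MLP] = {}
    logs: dict[float, list[float]] = {}
    for ri, res in enumerate(cfg.resolutions_mm):
        rng = np.random.default_rng((cfg.seed * 9973 + ri) % (2 ** 31 - 1))
        envs = []
        for vol, gt in cases:
            rv = resample_isotropic(vol, res)
            target = (gt.landmarks[landmark_id] - rv.origin_mm) / res
            envs.append(_Env(_normalize(rv.voxels), target, res))

        net = _make_net(cfg, seed_offset=ri + 1)
        target_net = _make_net(cfg, seed_offset=ri + 1)
        target_net.copy_from(net)
        opt = Adam(net.params(), lr=cfg.learning_rate)
        half = cfg.patch_size // 2

        buf_s = np.zeros((cfg.replay_capacity, cfg.patch_size ** 3))
        buf_a = np.zeros(cfg.replay_capacity, dtype=np.int64)
        buf_r = np.zeros(cfg.replay_capacity)
        buf_s2 = np.zeros_like(buf_s)
        buf_done = np.zeros(cfg.replay_capacity)
        buf_n = 0
        buf_ptr = 0
        updates = 0
        ep_final_dist = []

        for ep in range(cfg.episodes):
            env = envs[int(rng.integers(len(envs)))]
            if ri == 0:
                pos = np.array([rng.integers(0, n) for n in env.shape])
            else:
                off = rng.integers(-cfg.fine_start_offset_voxels,
                                   cfg.fine_start_offset_voxels + 1, 3)
                pos = np.clip(np.round(env.target).astype(int) + off,
                              0, env.shape - 1)
            eps = cfg.epsilon_start + (cfg.epsilon_end - cfg.epsilon_start) * (
                ep / max(1, cfg.episodes - 1))
            s = env.state(pos, half)
            for _ in range(cfg.max_steps):
                if rng.random() < eps:
                    a = int(rng.integers(6))
                else:
                    a = int(np.argmax(net.forward(s[None], train=False)[0]))
                d_old = env.dist_mm(pos)
                pos2 = np.clip(pos + _ACTIONS[a], 0, env.shape - 1)
                d_new = env.dist_mm(pos2)
                done = d_new < res * cfg.terminal_bonus_voxels
                reward = (d_old - d_new) + (res if done else 0.0)
                s2 = env.state(pos2, half)

                buf_s[buf_ptr] = s
                buf_a[buf_ptr] = a
                buf_r[buf_ptr] = reward
                buf_s2[buf_ptr] = s2
                buf_done[buf_ptr] = float(done)
                buf_ptr = (buf_ptr + 1) % cfg.replay_capacity
                buf_n = min(buf_n + 1, cfg.replay_capacity)

                if buf_n >= cfg.batch_size:
                    idx = rng.integers(0, buf_n, cfg.batch_size)
                    q2 = target_net.forward(buf_s2[idx], train=False).max(axis=1)
                    tgt = buf_r[idx] + cfg.discount * q2 * (1.0 - buf_done[idx])
                    q = net.forward(buf_s[idx], train=True)
                    dq = np.zeros_like(q)
                    sel = (np.arange(cfg.batch_size), buf_a[idx])
                    dq[sel] = (q[sel] - tgt) / cfg.batch_size
                    net.backward_step(dq, opt)
                    updates += 1
                    if updates % cfg.target_sync == 0:
                        target_net.copy_from(net)

                pos, s = pos2, s2
                if done:
                    break
            ep_final_dist.append(env.dist_mm(pos))
        nets[res] = net
        logs[res] = [float(d) for d in ep_final_dist]
    return LandmarkAgents(landmark_id, cfg, nets, logs)


def _run_greedy(net: MLP, env: _Env, start: np.ndarray, half: int,
                max_steps: int) -> tuple[np.ndarray, bool]:
    """Greedy rollout; stops on a position cycle (oscillation at the target)."""
    pos = np.clip(start, 0, env.shape - 1).astype(int)
    seen = {tuple(pos)}
    for _ in range(max_steps):
        s = env.state(pos, half)
        a = int(np.argmax(net.forward(s[None], train=False)[0]))
        pos2 = np.clip(pos + _ACTIONS[a], 0, env.shape - 1)
        key = tuple(pos2)
        if key in seen:
            return pos2, True
        seen.add(key)
        pos = pos2
    return pos, False


def geometric_median(points: np.ndarray, tol: float = 1e-6,
                     max_iter: int = 200) -> np.ndarray:
    """Weiszfeld's algorithm; robust aggregate of terminal positions."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or len(pts) == 0:
        raise InputError("need a non-empty (n, d) point array")
    y = pts.mean(axis=0)
    for _ in range(max_iter):
        d = np.linalg.norm(pts - y, axis=1)
        if np.any(d < 1e-12):
            return pts[int(np.argmin(d))]
        w = 1.0 / d
        y_new = (pts * w[:, None]).sum(axis=0) / w.sum()
        if np.linalg.norm(y_new - y) < tol:
            return y_new
        y = y_new
    return y


def detect_landmarks(agents: LandmarkAgents | list[LandmarkAgents], v: Volume,
                     starts: int = 5, seed: int = 0) -> dict:
    """Coarse-to-fine landmark inference.

    The coarsest agent runs from ``starts`` random positions; terminal
    positions are pooled by geometric median and handed (with one-voxel
    jitter) to the next finer agent. Returns {name: (3,) mm point}; positions
    from rollouts that never terminated are still used but the landmark is
    flagged in ``result['_low_confidence']``.
    """
    agent_list = agents if isinstance(agents, list) else [agents]
    out: dict = {}
    low_conf: list[str] = []
    for ag in agent_list:
        rng = np.random.default_rng(seed)
        half = ag.cfg.patch_size // 2
        current_mm = None
        any_terminated = True
        for res in ag.cfg.resolutions_mm:
            rv = resample_isotropic(v, res)
            env = _Env(_normalize(rv.voxels), np.zeros(3), res)
            if current_mm is None:
                starts_vox = [np.array([rng.integers(0, n) for n in env.shape])
                              for _ in range(starts)]
            else:
                c = (current_mm - rv.origin_mm) / res
                starts_vox = [np.round(c).astype(int)]
                starts_vox += [np.round(c).astype(int) + rng.integers(-1, 2, 3)
                               for _ in range(starts - 1)]
            terms = []
            terminated = []
            for sv in starts_vox:
                p, ok = _run_greedy(ag.nets[res], env, sv, half, ag.cfg.max_steps)
                terms.append(p)
                terminated.append(ok)
            if not any(terminated):
                any_terminated = False
            agg = geometric_median(np.asarray(terms, dtype=float))
            current_mm = agg * res + rv.origin_mm
        out[ag.landmark_id] = current_mm
        if not any_terminated:
            low_conf.append(ag.landmark_id)
    out["_low_confidence"] = low_conf
    return out


def oracle_landmarks(gt: GroundTruth) -> dict:
    """Ground-truth passthrough provider."""
    return {k: np.asarray(p, dtype=float).copy() for k, p in gt.landmarks.items()}


def landmark_error(pred: dict, truth: dict) -> tuple[dict[str, float], float]:
    """Per-landmark Euclidean distance (mm) and their unweighted mean."""
    keys = [k for k in truth if k in pred and not k.startswith("_")]
    if not keys:
        raise InputError("no shared landmark keys")
    per = {k: float(np.linalg.norm(np.asarray(pred[k], float)
                                   - np.asarray(truth[k], float))) for k in keys}
    return per, float(np.mean(list(per.values())))


def landmarks_to_json(lm: dict, path: str | Path) -> None:
    payload = {k: [float(x) for x in v] for k, v in lm.items() if not k.startswith("_")}
    Path(path).write_text(json.dumps(payload, indent=2))


def landmarks_from_json(path: str | Path) -> dict:
    return {k: np.asarray(v, dtype=float)
            for k, v in json.loads(Path(path).read_text()).items()}
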