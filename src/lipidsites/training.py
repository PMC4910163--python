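"""The four-stage group-based training pipeline.

Training proceeds through four sequential stages, each refining the scoring
function while the others are held fixed:

1. **Site clustering** — positive sites are split into motif groups
   (myristoylation, prenylation) or k-means clusters (palmitoylation).
2. **Motif length selection (MLS)** — the scoring window (m, n) is chosen
   from a candidate grid by maximising leave-one-out sensitivity at 90%
   specificity with baseline weights.
3. **Weight training (WT)** — per-position weight changes ``dw_i`` are
   optimised by ALC-PSO against the same LOO Sn@Sp90 objective.
4. **Matrix mutation (MaM)** — symmetric substitution-score changes
   ``dS(a, b)`` over the 210 standard-residue pairs are optimised likewise.

Because the optimizer always evaluates the zero-delta point first and returns
the best-ever position, the objective after WT can never fall below the
untrained baseline, and after MaM never below the post-WT value.

The LOO inside the objective is exact without retraining: a positive peptide
is scored against its own group with itself removed (a closed-form correction
of the group mean), negatives against the full group.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from . import __version__
from .seqio import (
    MOD_TYPES,
    ModSite,
    PeptideWindow,
    Protein,
    enumerate_candidates,
    extract_window,
)
from .scoring import (
    N_PAIRS,
    N_SYMBOLS,
    STANDARD_PAIRS,
    SubstitutionMatrix,
    WeightVector,
    encode_many,
    _BLOSUM62,
    _INDEX,
)
from .grouping import GroupModel, classify_site, kmeans_cluster
from .alcpso import PsoConfig, optimize

logger = logging.getLogger(__name__)

#: Full training-context window half-widths: 30 residues each side.
CONTEXT = 30

DEFAULT_MLS_GRID: tuple[tuple[int, int], ...] = tuple(
    (m, n)
    for m in (1, 3, 5, 7, 10, 15, 20, 25, 30)
    for n in (1, 3, 5, 7, 10, 15, 20, 25, 30)
)

#: Specificity levels defining the three prediction stringencies.
SP_LEVELS: dict[str, float] = {"high": 0.95, "medium": 0.90, "low": 0.85}


class TrainingError(RuntimeError):
    pass


@dataclass(frozen=True)
class TrainConfig:
    """Knobs of the training pipeline; all stages are deterministic given
    ``seed``."""

    seed: int = 0
    swarm_size: int = 20
    pso_iterations: int = 100
    stagnation_limit: int | None = 50
    mls_grid: tuple[tuple[int, int], ...] = DEFAULT_MLS_GRID
    cluster_window: tuple[int, int] = (10, 10)
    kmeans_k: int = 3
    kmeans_restarts: int = 5
    wt_box: float = 1.0   # dw in [-wt_box, +wt_box]
    mam_box: float = 4.0  # dS in [-mam_box, +mam_box]
    sp_target: float = 0.90
    min_group_size: int = 3
    pooled_objective: bool = False

    def pso_config(self, seed: int) -> PsoConfig:
        return PsoConfig(
            swarm_size=self.swarm_size,
            max_iterations=self.pso_iterations,
            stagnation_limit=self.stagnation_limit,
            seed=seed,
        )


@dataclass
class TrainingSet:
    """Positive and negative sites of one type, with full-context windows."""

    mod_type: str
    positives: list[tuple[str, int, PeptideWindow]]
    negatives: list[tuple[str, int, PeptideWindow]]

    @property
    def residue(self) -> str:
        return MOD_TYPES[self.mod_type]


def build_training_set(
    proteins: Sequence[Protein],
    sites: Sequence[ModSite],
    mod_type: str,
) -> TrainingSet:
    """Positives are the annotated sites of ``mod_type``; negatives every
    other candidate residue (C or G as appropriate) in the same substrate
    proteins."""
    if mod_type not in MOD_TYPES:
        raise TrainingError(f"unknown mod_type {mod_type!r}")
    residue = MOD_TYPES[mod_type]
    by_id = {p.id: p for p in proteins}
    pos_keys = {
        (s.protein_id, s.position) for s in sites if s.mod_type == mod_type
    }
    if not pos_keys:
        raise TrainingError(f"no positive sites for {mod_type}")
    substrates = sorted({pid for pid, _ in pos_keys})
    positives: list[tuple[str, int, PeptideWindow]] = []
    negatives: list[tuple[str, int, PeptideWindow]] = []
    for pid in substrates:
        prot = by_id[pid]
        for pos in enumerate_candidates(prot, residue):
            w = extract_window(prot, pos, CONTEXT, CONTEXT)
            if (pid, pos) in pos_keys:
                positives.append((pid, pos, w))
            else:
                negatives.append((pid, pos, w))
    return TrainingSet(mod_type=mod_type, positives=positives, negatives=negatives)


# ---------------------------------------------------------------------------
# vectorised scoring engine
# ---------------------------------------------------------------------------

_PAIR_I = np.array([_INDEX[a] for a, _ in STANDARD_PAIRS])
_PAIR_J = np.array([_INDEX[b] for _, b in STANDARD_PAIRS])


def apply_pair_deltas(pair_deltas: np.ndarray) -> np.ndarray:
    """Dense (22, 22) matrix: BLOSUM62 base plus symmetric pair deltas."""
    D = np.zeros((N_SYMBOLS, N_SYMBOLS))
    D[_PAIR_I, _PAIR_J] = pair_deltas
    D[_PAIR_J, _PAIR_I] = pair_deltas
    return _BLOSUM62 + D


def position_profile(codes: np.ndarray) -> np.ndarray:
    """(22, L) per-position symbol frequency profile of a peptide group."""
    n, L = codes.shape
    F = np.zeros((N_SYMBOLS, L))
    cols = np.broadcast_to(np.arange(L), (n, L))
    np.add.at(F, (codes, cols), 1.0)
    return F / n


def group_scores(
    M: np.ndarray, F: np.ndarray, w: np.ndarray, Q: np.ndarray
) -> np.ndarray:
    """Scores of query windows ``Q`` (codes, shape (q, L)) against a group
    summarised by its frequency profile ``F`` — equal to the mean over the
    group's peptides of the position-weighted substitution score."""
    P = M @ F  # (22, L): mean substitution score per query symbol, position
    g = P[Q, np.arange(Q.shape[1])[None, :]]
    return g @ w


def loo_scores_for_members(
    M: np.ndarray, F: np.ndarray, w: np.ndarray, codes: np.ndarray
) -> np.ndarray:
    """LOO scores of a group's own members: the group mean with the member's
    self-comparison removed. Groups of one get ``-inf``."""
    n = codes.shape[0]
    full = group_scores(M, F, w, codes)
    if n == 1:
        return np.full(1, -np.inf)
    self_terms = (M[codes, codes] * w[None, :]).sum(axis=1)
    return (n * full - self_terms) / (n - 1)


def sn_at_sp(pos_scores: np.ndarray, neg_scores: np.ndarray, sp: float) -> float:
    """Sensitivity at the score cutoff granting specificity >= ``sp``.

    The cutoff is placed just above the negative order statistic that leaves
    at most ``floor((1 - sp) * n_neg)`` negatives called positive.
    """
    n_neg = neg_scores.size
    allowed = int(math.floor((1.0 - sp) * n_neg))
    if allowed >= n_neg:
        return float(np.mean(pos_scores > -np.inf))
    v = np.partition(neg_scores, n_neg - 1 - allowed)[n_neg - 1 - allowed]
    return float(np.mean(pos_scores > v))


def sp_cutoff(neg_scores: np.ndarray, level: float) -> float:
    """Minimal observed score achieving specificity >= ``level`` under the
    closed lower bound convention (call positive iff score >= cutoff).

    If no observed score achieves it (ties at the maximum), the cutoff is
    placed just above the maximal negative score, with a warning."""
    neg = np.sort(np.asarray(neg_scores, dtype=float))
    n = neg.size
    need = int(math.ceil(level * n))  # negatives that must fall below cutoff
    for c in np.unique(neg):
        if np.searchsorted(neg, c, side="left") >= need:
            return float(c)
    top = float(np.nextafter(neg[-1], np.inf))
    logger.warning(
        "specificity %.2f unreachable among observed scores; cutoff set "
        "above the maximal negative score", level,
    )
    return top


@dataclass
class _GroupState:
    """Mutable per-group training state on trimmed code matrices."""

    group_id: str
    kind: str
    member_idx: np.ndarray       # indices into ts.positives
    codes: np.ndarray            # (n_members, L)
    w: np.ndarray                # (L,)
    pair_deltas: np.ndarray      # (210,)

    @property
    def M(self) -> np.ndarray:
        return apply_pair_deltas(self.pair_deltas)

    @property
    def F(self) -> np.ndarray:
        return position_profile(self.codes)


def _trim_codes(codes61: np.ndarray, m: int, n: int) -> np.ndarray:
    if m > CONTEXT or n > CONTEXT:
        raise TrainingError(
            f"window ({m},{n}) exceeds stored context ({CONTEXT},{CONTEXT})"
        )
    return codes61[:, CONTEXT - m : CONTEXT + n + 1]


def _model_sn(
    states: Sequence[_GroupState], neg_codes: np.ndarray, sp: float
) -> float:
    """Pipeline-level objective: per-group Sp cutoffs, pooled sensitivity."""
    called = 0
    total = 0
    for st in states:
        M, F = st.M, st.F
        loo = loo_scores_for_members(M, F, st.w, st.codes)
        neg = group_scores(M, F, st.w, neg_codes)
        called += int(np.sum(loo > _sp_boundary(neg, sp)))
        total += st.codes.shape[0]
    return called / total if total else 0.0


def _sp_boundary(neg_scores: np.ndarray, sp: float) -> float:
    n_neg = neg_scores.size
    allowed = int(math.floor((1.0 - sp) * n_neg))
    if allowed >= n_neg:
        return -np.inf
    return float(np.partition(neg_scores, n_neg - 1 - allowed)[n_neg - 1 - allowed])


def group_objective_value(
    st: _GroupState, neg_codes: np.ndarray, sp: float = 0.90
) -> float:
    """The per-group training objective: LOO sensitivity of the group's
    members at the cutoff granting specificity >= ``sp`` on the negatives."""
    M, F = st.M, st.F
    loo = loo_scores_for_members(M, F, st.w, st.codes)
    neg = group_scores(M, F, st.w, neg_codes)
    return sn_at_sp(loo, neg, sp)


def assign_groups(
    proteins: Sequence[Protein],
    ts: TrainingSet,
    config: TrainConfig,
    seed: int,
) -> list[tuple[str, str, np.ndarray]]:
    """Label each positive with a group; returns (group_id, kind, indices).

    Groups smaller than ``config.min_group_size`` are merged into a
    non-consensus group (created if absent) with a warning.
    """
    by_id = {p.id: p for p in proteins}
    n = len(ts.positives)
    labels: list[str] = []
    kinds: dict[str, str] = {}
    if ts.mod_type == "PALM":
        k = min(config.kmeans_k, n)
        windows = [w.trim(*config.cluster_window) for _, _, w in ts.positives]
        ca = kmeans_cluster(
            windows, k=k, restarts=config.kmeans_restarts, seed=seed
        )
        labels = [f"cluster{int(lab)}" for lab in ca.labels]
        for c in range(k):
            kinds[f"cluster{c}"] = "kmeans-cluster"
    else:
        for pid, pos, _ in ts.positives:
            lab = classify_site(by_id[pid], pos, ts.mod_type)
            labels.append(lab)
            kinds[lab] = "nonconsensus" if lab == "nonconsensus" else "consensus"
    groups: dict[str, list[int]] = {}
    for i, lab in enumerate(labels):
        groups.setdefault(lab, []).append(i)
    small = [g for g, idx in groups.items() if len(idx) < config.min_group_size]
    if small and len(groups) > len(small):
        sink = "nonconsensus"
        groups.setdefault(sink, [])
        kinds[sink] = "nonconsensus"
        for g in small:
            if g == sink:
                continue
            logger.warning(
                "group %s has %d positives (< %d); merged into %s",
                g, len(groups[g]), config.min_group_size, sink,
            )
            groups[sink].extend(groups.pop(g))
            kinds.pop(g, None)
    return [
        (g, kinds[g], np.array(sorted(idx), dtype=np.intp))
        for g, idx in sorted(groups.items())
        if idx
    ]


def select_motif_length(
    ts: TrainingSet,
    group_defs: Sequence[tuple[str, str, np.ndarray]],
    candidates: Sequence[tuple[int, int]],
    sp: float = 0.90,
) -> tuple[int, int]:
    """Pick the (m, n) maximising LOO Sn@Sp with baseline weights and
    matrix; ties break toward the smaller window (m+n, then m)."""
    if not candidates:
        raise TrainingError("MLS candidate list is empty")
    pos61 = encode_many([w for _, _, w in ts.positives])
    neg61 = encode_many([w for _, _, w in ts.negatives])
    best_sn = -1.0
    best_mn: tuple[int, int] | None = None
    for m, n in sorted(candidates, key=lambda mn: (mn[0] + mn[1], mn[0], mn[1])):
        L = m + n + 1
        states = [
            _GroupState(
                group_id=g, kind=kind, member_idx=idx,
                codes=_trim_codes(pos61[idx], m, n),
                w=np.ones(L), pair_deltas=np.zeros(N_PAIRS),
            )
            for g, kind, idx in group_defs
        ]
        sn = _model_sn(states, _trim_codes(neg61, m, n), sp)
        if sn > best_sn:
            best_sn = sn
            best_mn = (m, n)
    assert best_mn is not None
    return best_mn


def _group_objective_wt(
    st: _GroupState, neg_codes: np.ndarray, sp: float
) -> Callable[[np.ndarray], np.ndarray]:
    """WT objective over a swarm of dw vectors. With the matrix frozen, both
    the LOO scores and the negative scores are matrix-vector products in w,
    so the heavy gathers are precomputed once."""
    M, F = st.M, st.F
    n, L = st.codes.shape
    ar = np.arange(L)[None, :]
    P = M @ F
    B = P[neg_codes, ar]                                  # (n_neg, L)
    if n > 1:
        pos_g = P[st.codes, ar]                           # (n, L)
        self_g = M[st.codes, st.codes]                    # (n, L)
        A = (n * pos_g - self_g) / (n - 1)                # LOO gather
    else:
        A = None

    def obj(DW: np.ndarray) -> np.ndarray:
        W = np.clip(1.0 + DW, 0.0, None)                  # (swarm, L)
        negS = B @ W.T                                    # (n_neg, swarm)
        posS = A @ W.T if A is not None else None
        out = np.empty(W.shape[0])
        for j in range(W.shape[0]):
            p = posS[:, j] if posS is not None else np.full(1, -np.inf)
            out[j] = sn_at_sp(p, negS[:, j], sp)
        return out

    return obj


def _group_objective_mam(
    st: _GroupState, neg_codes: np.ndarray, sp: float
) -> Callable[[np.ndarray], np.ndarray]:
    """MaM objective over a swarm of dS pair-delta vectors."""
    F = st.F
    codes = st.codes
    n, L = codes.shape
    w = st.w
    ar = np.arange(L)[None, :]

    def obj(DS: np.ndarray) -> np.ndarray:
        out = np.empty(DS.shape[0])
        for j in range(DS.shape[0]):
            M = apply_pair_deltas(DS[j])
            P = M @ F
            full = (P[codes, ar] * w[None, :]).sum(axis=1)
            if n > 1:
                selfs = (M[codes, codes] * w[None, :]).sum(axis=1)
                loo = (n * full - selfs) / (n - 1)
            else:
                loo = np.full(1, -np.inf)
            neg = (P[neg_codes, ar] * w[None, :]).sum(axis=1)
            out[j] = sn_at_sp(loo, neg, sp)
        return out

    return obj


def train_weights(
    st: _GroupState, neg_codes: np.ndarray, config: TrainConfig, seed: int
) -> _GroupState:
    """Optimise per-position weight deltas for one group (WT stage).

    A zero-iteration budget leaves the all-ones weights untouched."""
    if config.pso_iterations == 0:
        return st
    L = st.codes.shape[1]
    obj = _group_objective_wt(st, neg_codes, config.sp_target)
    res = optimize(
        obj, d=L, bounds=[(-config.wt_box, config.wt_box)] * L,
        config=config.pso_config(seed), init=np.zeros(L),
    )
    st.w = np.clip(1.0 + res.position, 0.0, None)
    return st


def mutate_matrix(
    st: _GroupState, neg_codes: np.ndarray, config: TrainConfig, seed: int
) -> _GroupState:
    """Optimise symmetric substitution-score deltas for one group (MaM).

    A zero-iteration budget leaves BLOSUM62 intact."""
    if config.pso_iterations == 0:
        return st
    obj = _group_objective_mam(st, neg_codes, config.sp_target)
    res = optimize(
        obj, d=N_PAIRS, bounds=[(-config.mam_box, config.mam_box)] * N_PAIRS,
        config=config.pso_config(seed), init=np.zeros(N_PAIRS),
    )
    st.pair_deltas = res.position.copy()
    return st


# ---------------------------------------------------------------------------
# the model container
# ---------------------------------------------------------------------------


@dataclass
class PredictorModel:
    """A trained per-type predictor: window, groups, thresholds, metadata."""

    mod_type: str
    m: int
    n: int
    groups: list[GroupModel]
    seed: int
    config: TrainConfig
    data_checksum: str
    version: str = __version__

    def to_dict(self) -> dict:
        return {
            "format": "lipidsites-model",
            "format_version": 1,
            "version": self.version,
            "mod_type": self.mod_type,
            "window": {"m": self.m, "n": self.n},
            "seed": self.seed,
            "data_checksum": self.data_checksum,
            "config": {
                **{k: v for k, v in asdict(self.config).items()
                   if k not in ("mls_grid", "cluster_window")},
                "mls_grid": [list(mn) for mn in self.config.mls_grid],
                "cluster_window": list(self.config.cluster_window),
            },
            "groups": [
                {
                    "group_id": g.group_id,
                    "kind": g.kind,
                    "member_indices": [int(i) for i in g.member_indices],
                    "peptides": [
                        {"residues": p.residues, "center_pos": p.center_pos}
                        for p in g.positives
                    ],
                    "weights": [float(x) for x in g.weights.weights],
                    "pair_deltas": [float(x) for x in g.matrix.pair_deltas()],
                    "thresholds": {k: float(v) for k, v in sorted(g.thresholds.items())},
                }
                for g in self.groups
            ],
        }

    def save(self, path: str | Path) -> None:
        text = json.dumps(self.to_dict(), sort_keys=True, indent=1)
        Path(path).write_text(text + "\n")

    @classmethod
    def from_dict(cls, d: dict) -> "PredictorModel":
        if d.get("format") != "lipidsites-model":
            raise TrainingError("not a lipidsites model file")
        m, n = d["window"]["m"], d["window"]["n"]
        cfg_d = dict(d["config"])
        cfg_d["mls_grid"] = tuple(tuple(mn) for mn in cfg_d["mls_grid"])
        cfg_d["cluster_window"] = tuple(cfg_d["cluster_window"])
        config = TrainConfig(**cfg_d)
        groups = [
            GroupModel(
                group_id=g["group_id"],
                mod_type=d["mod_type"],
                kind=g["kind"],
                positives=[
                    PeptideWindow(center_pos=p["center_pos"], m=m, n=n,
                                  residues=p["residues"])
                    for p in g["peptides"]
                ],
                weights=WeightVector(np.array(g["weights"])),
                matrix=SubstitutionMatrix.from_pair_deltas(np.array(g["pair_deltas"])),
                thresholds=dict(g["thresholds"]),
                member_indices=[int(i) for i in g["member_indices"]],
            )
            for g in d["groups"]
        ]
        return cls(
            mod_type=d["mod_type"], m=m, n=n, groups=groups, seed=d["seed"],
            config=config, data_checksum=d["data_checksum"],
            version=d.get("version", "unknown"),
        )

    @classmethod
    def load(cls, path: str | Path) -> "PredictorModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def dataset_checksum(
    proteins: Sequence[Protein], sites: Sequence[ModSite]
) -> str:
    h = hashlib.sha256()
    for p in sorted(proteins, key=lambda p: p.id):
        h.update(f">{p.id}\n{p.sequence}\n".encode())
    for s in sorted(sites, key=lambda s: s.key):
        h.update(f"{s.protein_id}\t{s.position}\t{s.residue}\t{s.mod_type}\n".encode())
    return h.hexdigest()


def _states_to_groups(
    ts: TrainingSet,
    states: Sequence[_GroupState],
    neg_codes: np.ndarray,
    m: int,
    n: int,
) -> list[GroupModel]:
    groups = []
    for st in states:
        neg = group_scores(st.M, st.F, st.w, neg_codes)
        thresholds = {
            name: sp_cutoff(neg, level) for name, level in SP_LEVELS.items()
        }
        peptides = [ts.positives[i][2].trim(m, n) for i in st.member_idx]
        groups.append(
            GroupModel(
                group_id=st.group_id,
                mod_type=ts.mod_type,
                kind=st.kind,
                positives=peptides,
                weights=WeightVector(st.w.copy()),
                matrix=SubstitutionMatrix.from_pair_deltas(st.pair_deltas.copy()),
                thresholds=thresholds,
                member_indices=[int(i) for i in st.member_idx],
            )
        )
    return groups


def train(
    proteins: Sequence[Protein],
    sites: Sequence[ModSite],
    mod_type: str,
    config: TrainConfig | None = None,
) -> PredictorModel:
    """Run the full pipeline: clustering, MLS, WT, MaM, calibration."""
    config = config or TrainConfig()
    root = np.random.SeedSequence(config.seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(64)]

    stage = "build_training_set"
    try:
        ts = build_training_set(proteins, sites, mod_type)
        stage = "clustering"
        group_defs = assign_groups(proteins, ts, config, seed=seeds[0])
        stage = "motif length selection"
        m, n = select_motif_length(ts, group_defs, config.mls_grid, config.sp_target)
        pos61 = encode_many([w for _, _, w in ts.positives])
        neg61 = encode_many([w for _, _, w in ts.negatives])
        neg_codes = _trim_codes(neg61, m, n)
        L = m + n + 1
        states = [
            _GroupState(
                group_id=g, kind=kind, member_idx=idx,
                codes=_trim_codes(pos61[idx], m, n),
                w=np.ones(L), pair_deltas=np.zeros(N_PAIRS),
            )
            for g, kind, idx in group_defs
        ]
        stage = "weight training"
        for gi, st in enumerate(states):
            train_weights(st, neg_codes, config, seed=seeds[1 + gi])
        stage = "matrix mutation"
        for gi, st in enumerate(states):
            mutate_matrix(st, neg_codes, config, seed=seeds[32 + gi])
        stage = "threshold calibration"
        groups = _states_to_groups(ts, states, neg_codes, m, n)
    except TrainingError:
        raise
    except Exception as exc:  # noqa: BLE001 - annotate the failing stage
        raise TrainingError(f"training stage '{stage}' failed: {exc}") from exc

    return PredictorModel(
        mod_type=mod_type, m=m, n=n, groups=groups, seed=config.seed,
        config=config, data_checksum=dataset_checksum(proteins, sites),
    )


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------


def _group_engine(g: GroupModel) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    codes = encode_many(g.positives)
    return g.matrix.as_array(), position_profile(codes), g.weights.weights


def score_candidates(
    model: PredictorModel, protein: Protein
) -> list[tuple[int, str, dict[str, float]]]:
    """Per-candidate raw scores against every group of the model's type.

    Returns (position, peptide, {group_id: score}) triples.
    """
    residue = MOD_TYPES[model.mod_type]
    positions = enumerate_candidates(protein, residue)
    if not positions:
        return []
    windows = [extract_window(protein, p, model.m, model.n) for p in positions]
    Q = encode_many(windows)
    per_group = {}
    for g in model.groups:
        M, F, w = _group_engine(g)
        per_group[g.group_id] = group_scores(M, F, w, Q)
    return [
        (pos, win.residues, {gid: float(sc[i]) for gid, sc in per_group.items()})
        for i, (pos, win) in enumerate(zip(positions, windows))
    ]


def predict(
    model: PredictorModel,
    proteins: Sequence[Protein],
    stringency: str = "medium",
) -> list[ModSite]:
    """Score every candidate residue against all groups; report sites whose
    best margin (score minus the group's stringency cutoff) is >= 0."""
    if stringency not in SP_LEVELS:
        raise ValueError(f"stringency must be one of {sorted(SP_LEVELS)}")
    out: list[ModSite] = []
    for prot in proteins:
        for pos, peptide, scores in score_candidates(model, prot):
            best = max(
                (
                    (scores[g.group_id] - g.thresholds[stringency],
                     g.group_id, scores[g.group_id], g.thresholds[stringency])
                    for g in model.groups
                ),
                key=lambda t: t[0],
            )
            margin, gid, score, cut = best
            if margin >= 0:
                out.append(
                    ModSite(
                        protein_id=prot.id, position=pos,
                        residue=MOD_TYPES[model.mod_type],
                        mod_type=model.mod_type, evidence="predicted",
                        score=score, cutoff=cut, group_id=gid, peptide=peptide,
                    )
                )
    return out


def write_predictions(
    sites: Sequence[ModSite], path: str | Path,
    header_lines: Sequence[str] = (),
) -> None:
    """Prediction TSV: id, position, peptide, type, group, score, cutoff."""
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("protein_id\tposition\tpeptide\tmod_type\tgroup\tscore\tcutoff\n")
        for s in sites:
            fh.write(
                f"{s.protein_id}\t{s.position}\t{s.peptide}\t{s.mod_type}\t"
                f"{s.group_id}\t{s.score:.6f}\t{s.cutoff:.6f}\n"
            )
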