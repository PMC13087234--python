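"""Federated orchestration: registration, rounds, aggregation, evaluation.

Hospitals hold heterogeneous synthetic cohorts but share one GNN architecture
(identical parameter shapes, so gradient vectors are aggregable). A round
samples ceil(participation_ratio * n) hospitals; each trains locally for a
few epochs, protects its round gradient (RLS + additive masking), signs, and
submits. The server authenticates (J2 submissions are excluded and logged),
recovers gradients, cluster-aggregates them (CHI-initialized Zhonghua-
distance k-means), evaluates each cluster's aggregate on a server-held
validation cohort, and dispatches the per-cluster global gradient back to
cluster members, who blend it with their replay buffer via polynomial-decay
experience replay. Every step lands on the hash-chained ledger.

Before round 1 every hospital performs a local warm-up fit, mirroring the
deployment story in which local models exist before federation begins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import exprdsa, hrlse
from .clustering import ZDConfig, cluster_aggregate
from .errors import ArgumentError, DataError
from .gnn import GNNClassifier, GNNParams, TrainConfig
from .ledger import Ledger
from .metrics import ConfusionCounts, classification_metrics, cluster_quality, jain_index
from .preprocess import EHRTable, preprocess_pipeline
from .replay import DecayConfig, ReplayBuffer, continual_update
from .synthetic import default_cohort_spec, generate_cohort
from .tcg import build_node_matrix, build_tcg, extract_tcg_features


@dataclass
class FederationConfig:
    n_hospitals: int = 5
    rounds: int = 10
    participation_ratio: float = 0.3
    epochs_per_client: int = 5
    warmup_epochs: int = 100
    batch_size: int = 32
    records_per_hospital: int = 500
    noniid_alpha: float = 0.5  # 0.5 mild, 0.1 severe
    p_clusters: int = 2
    learning_rate: float = 0.001
    hidden: int = 32
    n_layers: int = 3
    k_neighbours: int = 8
    tcg_threshold: float = 0.3
    tcg_max_lag: int = 3
    tcg_window: int = 32
    decay_lam: float = 0.05
    decay_tau: float = 1.0
    buffer_capacity: int = 20
    rls_q: float = 1.0
    #: coefficient multiplier of the cohorts' label model; the default keeps
    #: the tasks close to separable so federation quality is measurable
    label_scale: float = 6.0
    #: missingness of the simulated cohorts; 0 keeps the tasks separable
    #: (imputation noise replaces cells with unrelated neighbours' values)
    missing_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 < self.participation_ratio <= 1.0):
            raise ArgumentError("participation_ratio must lie in (0, 1]")
        if self.n_hospitals < 1:
            raise ArgumentError("n_hospitals must be >= 1")
        if self.rounds < 0:
            raise ArgumentError("rounds must be >= 0")

    def n_participants(self) -> int:
        return math.ceil(self.participation_ratio * self.n_hospitals)


def partition_noniid(labels: np.ndarray, n_clients: int, alpha: float,
                     seed: int = 0, max_tries: int = 100) -> list[np.ndarray]:
    """Dirichlet(alpha) label-skewed partition into nonempty shards.

    For each class, its records are split among clients with proportions
    drawn from Dirichlet(alpha); small alpha concentrates classes on few
    clients. Every record lands in exactly one shard; draws are repeated
    (up to ``max_tries``) until all shards are nonempty.
    """
    labels = np.asarray(labels)
    n = len(labels)
    if n_clients < 1 or alpha <= 0:
        raise ArgumentError("need n_clients >= 1 and alpha > 0")
    if n_clients > n:
        raise ArgumentError("more clients than records")
    rng = np.random.default_rng(seed)
    classes = np.unique(labels)
    for _ in range(max_tries):
        shards: list[list[int]] = [[] for _ in range(n_clients)]
        for cls in classes:
            idx = np.flatnonzero(labels == cls)
            rng.shuffle(idx)
            props = rng.dirichlet(np.full(n_clients, alpha))
            cuts = (np.cumsum(props)[:-1] * len(idx)).astype(int)
            for shard, part in zip(shards, np.split(idx, cuts)):
                shard.extend(part.tolist())
        if all(shards):
            return [np.sort(np.array(s)) for s in shards]
    raise DataError("could not draw nonempty shards; raise alpha or shrink n_clients")


@dataclass
class HospitalNode:
    hospital_id: str
    task: str
    identity: exprdsa.HospitalIdentity
    keys: hrlse.KeyPair
    model: GNNClassifier
    params: GNNParams
    buffer: ReplayBuffer
    decay: DecayConfig
    table: EHRTable


@dataclass
class GlobalServer:
    registry: dict[str, exprdsa.HospitalIdentity] = field(default_factory=dict)
    keystore: dict[str, hrlse.KeyPair] = field(default_factory=dict)
    validation_model: GNNClassifier | None = None

    def register(self, identity: exprdsa.HospitalIdentity, keys: hrlse.KeyPair) -> None:
        if identity.hospital_id in self.registry:
            raise ArgumentError(f"hospital id {identity.hospital_id!r} already registered")
        self.registry[identity.hospital_id] = identity
        self.keystore[identity.hospital_id] = keys

    def login(self, hospital_id: str, password: str) -> bool:
        ident = self.registry.get(hospital_id)
        return bool(ident and ident.check_password(password))


@dataclass
class RoundLog:
    """Audit record of one round: ciphertexts and aggregates only."""

    round_index: int
    participants: list[str]
    authenticated: list[str]
    excluded: list[str]
    cipher_digests: dict[str, str]
    assignment: dict[str, int]
    global_accuracy: dict[int, float]
    mean_loss: float


@dataclass
class SimulationResults:
    config: FederationConfig
    per_hospital: dict[str, dict]
    round_logs: list[RoundLog]
    jain: float
    mean_final_accuracy: float
    loss_convergence_rate: float
    clustering_quality: dict[str, float]
    ledger_ok: bool
    ledger_length: int

    def summary(self) -> str:
        cfg = self.config
        lines = [
            "Federated clinical-event-prediction simulation",
            "==============================================",
            f"hospitals: {cfg.n_hospitals}  rounds: {cfg.rounds}  "
            f"participation: {cfg.participation_ratio}  clusters: {cfg.p_clusters}",
            f"records/hospital: {cfg.records_per_hospital}  "
            f"epochs/client: {cfg.epochs_per_client}  seed: {cfg.seed}",
            "",
            f"{'hospital':<12}{'task':<22}{'acc':>7}{'prec':>7}{'rec':>7}{'F1':>7}",
        ]
        for hid, m in self.per_hospital.items():
            lines.append(f"{hid:<12}{m['task']:<22}{m['accuracy']:>7.3f}"
                         f"{m['precision']:>7.3f}{m['recall']:>7.3f}{m['f_measure']:>7.3f}")
        lines += [
            "",
            f"mean final local test accuracy: {self.mean_final_accuracy:.4f}",
            f"Jain fairness over accuracies:  {self.jain:.4f}",
            f"loss convergence rate:          {self.loss_convergence_rate:+.5f} /round",
            f"gradient clustering silhouette: {self.clustering_quality.get('silhouette', float('nan')):.4f}",
            f"ledger: {self.ledger_length} blocks, verification "
            f"{'passed' if self.ledger_ok else 'FAILED'}",
        ]
        return "\n".join(lines)


TASKS = ("heart-failure-like", "stroke-like", "cirrhosis-like",
         "kidney-disease-like", "diabetes-like")


def _build_hospital(idx: int, cfg: FederationConfig, seed: int) -> HospitalNode:
    task = TASKS[idx % len(TASKS)]
    spec = default_cohort_spec(n_records=cfg.records_per_hospital,
                               missing_rate=cfg.missing_rate, seed=seed,
                               label_scale=cfg.label_scale)
    raw = EHRTable(generate_cohort(spec))
    table, _ = preprocess_pipeline(raw)
    graph = build_tcg(table.features, max_lag=cfg.tcg_max_lag,
                      threshold=cfg.tcg_threshold, window=cfg.tcg_window,
                      node_names=table.feature_columns)
    K = build_node_matrix(table.features, extract_tcg_features(graph))
    tcfg = TrainConfig(learning_rate=cfg.learning_rate, batch_size=cfg.batch_size,
                       epochs=cfg.epochs_per_client, hidden=cfg.hidden,
                       n_layers=cfg.n_layers, k_neighbours=cfg.k_neighbours,
                       seed=seed)
    model = GNNClassifier(K, table.labels, tcfg)
    hid = f"hospital-{idx + 1}"
    identity = exprdsa.HospitalIdentity.register(
        hid, f"pw-{hid}-{cfg.seed}", public_key={},
        salt=seed.to_bytes(8, "big") + b"salt")
    keys = hrlse.keygen(seed, key_id=hid)
    identity = exprdsa.HospitalIdentity(hid, identity.password_digest,
                                        identity.salt, keys.public())
    buffer = ReplayBuffer(capacity=cfg.buffer_capacity, lam=cfg.decay_lam, tau=cfg.decay_tau)
    return HospitalNode(hid, task, identity, keys, model, model.init_params(),
                        buffer, DecayConfig(cfg.decay_lam, cfg.decay_tau), table)


class FederationSimulation:
    """End-to-end multi-round federation over synthetic cohorts."""

    def __init__(self, config: FederationConfig | None = None,
                 ledger_path=None):
        self.config = config or FederationConfig()
        self.config.validate()
        self.ledger = Ledger(ledger_path)
        self.server = GlobalServer()
        self.hospitals: list[HospitalNode] = []
        self.round_logs: list[RoundLog] = []
        self._rng = np.random.default_rng(self.config.seed)
        self._last_assignment = None
        self._last_gradients = None

    # -- setup ------------------------------------------------------------

    def setup(self) -> None:
        cfg = self.config
        base = cfg.seed % (2 ** 20)
        for i in range(cfg.n_hospitals):
            node = _build_hospital(i, cfg, seed=base * 1000 + i + 1)
            self.server.register(node.identity, node.keys)
            self.ledger.record(node.hospital_id, "registration",
                               {"id": node.hospital_id, "key": node.keys.key_id})
            ok = self.server.login(node.hospital_id, f"pw-{node.hospital_id}-{cfg.seed}")
            self.ledger.record(node.hospital_id, "login", {"ok": ok})
            self.hospitals.append(node)
        # server-held validation cohort for global prediction
        val_seed = base * 1000 + 999
        spec = default_cohort_spec(n_records=max(cfg.records_per_hospital // 2, 50),
                                   missing_rate=0.0, seed=val_seed,
                                   label_scale=cfg.label_scale)
        table, _ = preprocess_pipeline(EHRTable(generate_cohort(spec)))
        graph = build_tcg(table.features, max_lag=cfg.tcg_max_lag,
                          threshold=cfg.tcg_threshold, window=cfg.tcg_window)
        K = build_node_matrix(table.features, extract_tcg_features(graph))
        self.server.validation_model = GNNClassifier(
            K, table.labels, TrainConfig(hidden=cfg.hidden, n_layers=cfg.n_layers,
                                         k_neighbours=cfg.k_neighbours, seed=val_seed))

    def warmup(self) -> None:
        """Initial local fit for every hospital before federation begins."""
        for node in self.hospitals:
            res = node.model.fit(node.params, epochs=self.config.warmup_epochs)
            node.params = res.params
            # the replay buffer holds federated-round gradients only; the
            # warm-up delta is far larger than a round delta and would
            # dominate every later blend
            self.ledger.record(node.hospital_id, "local_training",
                               {"phase": "warmup", "loss": res.loss_history[-1]})

    # -- rounds -----------------------------------------------------------

    def run_round(self, round_index: int, tamper: dict[str, str] | None = None) -> RoundLog:
        """One federated round; ``tamper`` maps hospital id -> claimed id."""
        cfg = self.config
        tamper = tamper or {}
        k = cfg.n_participants()
        participants = [self.hospitals[i] for i in
                        sorted(self._rng.choice(cfg.n_hospitals, size=k, replace=False))]

        submissions = []  # (node, cipher, signature, claimed_id)
        for node in participants:
            res = node.model.fit(node.params, epochs=cfg.epochs_per_client)
            node.params = res.params  # keep the locally trained update
            self.ledger.record(node.hospital_id, "local_training",
                               {"round": round_index, "loss": res.loss_history[-1]})
            nonce = f"{node.hospital_id}-round-{round_index}"
            cipher = hrlse.protect_gradient(res.gradient, node.keys, nonce, cfg.rls_q)
            self.ledger.record(node.hospital_id, "privacy_preservation",
                               {"round": round_index, "nonce": nonce,
                                "length": cipher.length})
            claimed = tamper.get(node.hospital_id, node.hospital_id)
            signature = exprdsa.sign(claimed, node.keys.public())
            submissions.append((node, cipher, signature, claimed, res.loss_history[-1]))

        authenticated, excluded, losses = [], [], []
        gradients, ids = [], []
        cipher_digests = {}
        for node, cipher, signature, claimed, loss in submissions:
            registered = self.server.registry.get(claimed)
            if registered is None:
                result = exprdsa.AuthResult(False, "unregistered")
            else:
                result = exprdsa.verify(signature, claimed, registered.public_key)
            self.ledger.record(node.hospital_id, "authentication",
                               {"round": round_index, "claimed": claimed,
                                "J": "J1" if result.authenticated else "J2",
                                "reason": result.reason})
            from .ledger import payload_digest
            cipher_digests[node.hospital_id] = payload_digest(cipher.to_json_dict())
            if not result.authenticated:
                excluded.append(node.hospital_id)
                continue
            authenticated.append(node.hospital_id)
            losses.append(loss)
            keys = self.server.keystore[claimed]
            gradients.append(hrlse.recover_gradient(cipher, keys, cfg.rls_q))
            ids.append(node.hospital_id)

        if not authenticated:
            self.ledger.record("server", "aggregation",
                               {"round": round_index, "warning": "no authenticated participants"})
            log = RoundLog(round_index, [n.hospital_id for n in participants],
                           [], excluded, cipher_digests, {}, {}, float("nan"))
            self.round_logs.append(log)
            return log

        G = np.vstack(gradients)
        p = min(cfg.p_clusters, len(G))
        assignment = cluster_aggregate(G, p, ZDConfig(), seed=cfg.seed * 1000 + round_index,
                                       hospital_ids=ids)
        self._last_assignment, self._last_gradients = assignment, G
        self.ledger.record("server", "aggregation",
                           {"round": round_index, "clusters": int(assignment.n_clusters),
                            "members": assignment.assignment.tolist()})

        by_id = {n.hospital_id: n for n in self.hospitals}
        global_accuracy = {}
        for c in range(assignment.n_clusters):
            members = [ids[i] for i in assignment.members(c)]
            if not members:
                continue
            Y = assignment.aggregates[c]
            base = np.mean([by_id[m].params.flatten() for m in members], axis=0)
            template = by_id[members[0]].params
            vm = self.server.validation_model
            acc = vm.score(template.unflatten_like(base + Y))
            global_accuracy[c] = acc
            self.ledger.record("server", "global_prediction",
                               {"round": round_index, "cluster": c, "accuracy": acc})
            for i in assignment.members(c):
                node = by_id[ids[i]]
                flat = continual_update(node.params.flatten(), node.buffer, Y,
                                        node.decay, current_gradient=gradients[i])
                node.params = node.params.unflatten_like(flat)
                self.ledger.record(node.hospital_id, "continual_update",
                                   {"round": round_index, "cluster": c,
                                    "decay_b": node.decay.b})

        log = RoundLog(round_index, [n.hospital_id for n in participants],
                       authenticated, excluded, cipher_digests,
                       {ids[i]: int(assignment.assignment[i]) for i in range(len(ids))},
                       global_accuracy, float(np.mean(losses)))
        self.round_logs.append(log)
        return log

    # -- full run ---------------------------------------------------------

    def run(self) -> SimulationResults:
        cfg = self.config
        if not self.hospitals:
            self.setup()
            self.warmup()
        for r in range(1, cfg.rounds + 1):
            self.run_round(r)

        per_hospital = {}
        accuracies = []
        for node in self.hospitals:
            # evaluate on the hospital's held-out 20% (same seeded split as fit)
            split_rng = np.random.default_rng(node.model.config.seed)
            perm = split_rng.permutation(len(node.model.y))
            test_idx = perm[int(np.floor(0.8 * len(perm))):]
            acc = node.model.score(node.params, test_idx)
            conf = node.model.confusion(node.params, test_idx)
            m = classification_metrics(ConfusionCounts(**conf))
            per_hospital[node.hospital_id] = {"task": node.task, "accuracy": acc,
                                              "precision": m["precision"],
                                              "recall": m["recall"],
                                              "f_measure": m["f_measure"],
                                              "confusion": conf}
            accuracies.append(acc)

        round_losses = [lg.mean_loss for lg in self.round_logs
                        if not math.isnan(lg.mean_loss)]
        rate = ((round_losses[-1] - round_losses[0]) / (len(round_losses) - 1)
                if len(round_losses) > 1 else float("nan"))
        quality = {}
        if (self._last_assignment is not None
                and self._last_assignment.n_clusters >= 2
                and len(self._last_gradients) > self._last_assignment.n_clusters):
            try:
                quality = cluster_quality(self._last_gradients,
                                          self._last_assignment.assignment)
            except ArgumentError:
                quality = {}
        ok, _ = self.ledger.verify()
        return SimulationResults(cfg, per_hospital, self.round_logs,
                                 jain_index(np.array(accuracies)),
                                 float(np.mean(accuracies)), rate, quality,
                                 ok, len(self.ledger))


def run_simulation(config: FederationConfig | None = None) -> SimulationResults:
    """Convenience wrapper: build, warm up, run all rounds, evaluate."""
    return FederationSimulation(config).run()


def two_task_replay_experiment(seed: int, overwrite: bool = False,
                               lam: float = 0.05, tau: float = 1.0,
                               n_records: int = 400, phase_a_rounds: int = 4,
                               phase_b_rounds: int = 5,
                               epochs_per_round: int = 8) -> dict:
    """Sequential-task forgetting experiment: task A, then conflicting task B.

    Task A is the default separable cohort; task B flips the sign of every
    label-model coefficient, so adapting to B directly erases A. Phase A
    trains in rounds whose gradients fill the replay buffer; phase B rounds
    produce a "global" gradient Y from task-B training and update the model
    either by the polynomial-decay blend (MEPDR) or, with ``overwrite``, by
    pure global adoption (blend weight forced to 0). Returns the accuracy
    retained on task A's held-out split after phase B.
    """
    spec_a = default_cohort_spec(n_records=n_records, seed=seed * 2 + 1, label_scale=6.0)
    spec_b = default_cohort_spec(n_records=n_records, seed=seed * 2 + 2,
                                 label_scale=6.0, flip_sign=True)
    table_a, _ = preprocess_pipeline(EHRTable(generate_cohort(spec_a)))
    table_b, _ = preprocess_pipeline(EHRTable(generate_cohort(spec_b)))
    tcfg = TrainConfig(epochs=epochs_per_round, seed=seed)
    model_a = GNNClassifier(table_a.features, table_a.labels, tcfg)
    model_b = GNNClassifier(table_b.features, table_b.labels, tcfg)

    buffer = ReplayBuffer(lam=lam, tau=tau)
    decay = DecayConfig(lam=lam, tau=tau)
    params = model_a.init_params()
    for _ in range(phase_a_rounds):
        res = model_a.fit(params, epochs=epochs_per_round)
        params = res.params
        buffer.push(res.gradient, decay.b)

    split_rng = np.random.default_rng(seed)
    perm = split_rng.permutation(n_records)
    test_a = perm[int(np.floor(0.8 * n_records)):]
    acc_after_a = model_a.score(params, test_a)

    for _ in range(phase_b_rounds):
        res_b = model_b.fit(params, epochs=epochs_per_round)
        Y = res_b.gradient
        if overwrite:  # blend weight forced to 0: pure global adoption
            flat = params.flatten() + Y
            decay.b += 1
        else:
            flat = continual_update(params.flatten(), buffer, Y, decay)
        params = params.unflatten_like(flat)

    return {"accuracy_after_task_a": acc_after_a,
            "retained_accuracy_task_a": model_a.score(params, test_a),
            "accuracy_task_b": model_b.score(params)}
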