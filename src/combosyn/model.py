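"""Synergy model: fused cell/drug encoders, training and evaluation.

The model object follows the construct-then-fit convention: build a
:class:`SynergyModel` from an assembled dataset plus a :class:`TrainConfig`,
call :meth:`~SynergyModel.fit` to obtain a :class:`SynergyResults` carrying
the trained parameters, loss history, held-out metrics and a ``summary()``
table. ``cross_validate`` and ``run_ablation`` reuse the same machinery.

Per combination, the cell line's density tensor is encoded to ``z_e``, the
two drug graphs to ``z_a`` and ``z_b``; the concatenation feeds a two-
hidden-layer feedforward classifier with ReLU and dropout, ending in a
2-way log-softmax trained by negative log-likelihood. An optional scalar
regression head (for PCC/RMSE against continuous synergy scores) shares
the fusion trunk.

Ablation switches: with ``use_dkpe`` off the cell branch is a two-layer
perceptron on the raw expression vector; with ``use_gnn`` off each drug is
its mean-pooled 9-feature atom matrix through a linear map — minimal-
information stand-ins isolating each branch's contribution.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

from .cnn import CellEncoder, CellEncoderConfig
from .data import AssembledDataset
from .gnn import DrugEncoder, GnnConfig
from .metrics import EvalReport, metric_suite
from .nn.autodiff import Tensor, concat
from .nn.modules import Adam, Dropout, Linear, Module

__all__ = [
    "TrainConfig",
    "SynergyNet",
    "SynergyModel",
    "SynergyResults",
    "fuse_and_classify",
    "stratified_folds",
    "cross_validate",
    "run_ablation",
]


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters (names follow the training-table convention)."""

    batch_size: int = 300
    num_epochs: int = 100
    emb_dim: int = 100
    gnn_type: str = "gatv2"
    num_layer: int = 3
    heads: int = 1
    cnn_preset: str = "resnet54-paper"
    hidden_sizes: tuple = (1024, 512)
    dropout: float = 0.5
    lr: float = 1e-3
    use_dkpe: bool = True
    use_gnn: bool = True
    regression_head: bool = False
    pair_augment: bool = True
    share_drug_encoder: bool = True
    seed: int = 0

    @classmethod
    def tiny(cls, **overrides) -> "TrainConfig":
        """Desk-scale preset: trains in seconds per epoch on one CPU."""
        base = dict(
            batch_size=600,
            num_epochs=120,
            emb_dim=32,
            cnn_preset="tiny",
            hidden_sizes=(512, 256),
            dropout=0.2,
            lr=3e-3,
        )
        base.update(overrides)
        return cls(**base)


class _RawCellBranch(Module):
    """DKPE-off baseline: raw expression vector → 2-layer perceptron."""

    def __init__(self, in_dim: int, out_dim: int, rng):
        super().__init__()
        self.fc1 = Linear(in_dim, 2 * out_dim, rng)
        self.fc2 = Linear(2 * out_dim, out_dim, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).relu())


class _MeanAtomBranch(Module):
    """GNN-off baseline: mean-pooled 9-feature atom matrix → linear map."""

    def __init__(self, out_dim: int, rng):
        super().__init__()
        self.fc = Linear(9, out_dim, rng)

    def __call__(self, mean_feats: Tensor) -> Tensor:
        return self.fc(mean_feats)


class FusionHead(Module):
    """[z_e ∥ z_a ∥ z_b] → two ReLU+dropout hidden layers → 2-way log-softmax."""

    def __init__(self, in_dim: int, hidden: tuple, dropout: float, rng, regression: bool):
        super().__init__()
        h1, h2 = hidden
        self.fc1 = Linear(in_dim, h1, rng)
        self.fc2 = Linear(h1, h2, rng)
        self.out = Linear(h2, 2, rng)
        self.drop1 = Dropout(dropout, rng)
        self.drop2 = Dropout(dropout, rng)
        self.reg_out = Linear(h2, 1, rng) if regression else None

    def trunk(self, z: Tensor) -> Tensor:
        h = self.drop1(self.fc1(z).relu())
        return self.drop2(self.fc2(h).relu())

    def __call__(self, z: Tensor) -> Tensor:
        return self.out(self.trunk(z)).log_softmax(axis=-1)

    def regress(self, z: Tensor) -> Tensor:
        if self.reg_out is None:
            raise RuntimeError("regression head is disabled in this config")
        return self.reg_out(self.trunk(z)).reshape(-1)


def fuse_and_classify(z_e: Tensor, z_a: Tensor, z_b: Tensor, head: FusionHead) -> Tensor:
    """Log-probabilities (2-vector per sample) from the three embeddings."""
    one = z_e.ndim == 1
    if one:
        z_e, z_a, z_b = (z.reshape(1, -1) for z in (z_e, z_a, z_b))
    out = head(concat([z_e, z_a, z_b], axis=1))
    return out.reshape(-1) if one else out


class SynergyNet(Module):
    """The trainable network: cell branch + drug branch + fusion head."""

    def __init__(self, config: TrainConfig, gene_dim: int, rng: np.random.Generator):
        super().__init__()
        self.config = config
        d = config.emb_dim
        if config.use_dkpe:
            self.cell_branch = CellEncoder(CellEncoderConfig.preset(config.cnn_preset, out_dim=d), rng)
        else:
            self.cell_branch = _RawCellBranch(gene_dim, d, rng)
        if config.use_gnn:
            gcfg = GnnConfig(
                gnn_type=config.gnn_type,
                num_layer=config.num_layer,
                emb_dim=d,
                heads=config.heads,
            )
            self.drug_branch = DrugEncoder(gcfg, rng)
            if not config.share_drug_encoder:
                self.drug_branch_b = DrugEncoder(gcfg, rng)
        else:
            self.drug_branch = _MeanAtomBranch(d, rng)
        self.head = FusionHead(3 * d, config.hidden_sizes, config.dropout, rng, config.regression_head)

    # encoding helpers -------------------------------------------------------

    def _encode_cells(self, dataset: AssembledDataset, cell_ids: list[str]) -> Tensor:
        if self.config.use_dkpe:
            batch = np.stack([dataset.tensors[c].channels for c in cell_ids])
            return self.cell_branch.forward_batch(batch)
        mats = np.stack(
            [dataset.provenance["raw_expression"][c] for c in cell_ids]
        )
        return self.cell_branch(Tensor(mats))

    def _encode_drugs(self, dataset: AssembledDataset, drug_ids: list[str], second: bool = False) -> Tensor:
        if self.config.use_gnn:
            enc = self.drug_branch
            if second and not self.config.share_drug_encoder:
                enc = self.drug_branch_b
            return concat([enc(dataset.graphs[d]).reshape(1, -1) for d in drug_ids], axis=0)
        mats = np.stack([dataset.graphs[d].features_M.mean(axis=0) for d in drug_ids])
        return self.drug_branch(Tensor(mats))

    def forward_samples(self, dataset: AssembledDataset, idx: np.ndarray, swap: bool = False) -> Tensor:
        """Log-probabilities for dataset.samples[idx] (shape |idx|×2).

        Each unique cell line and drug in the batch is encoded once and the
        per-sample rows gathered from those shared embeddings.
        """
        samples = [dataset.samples[i] for i in idx]
        cells = sorted({s[0] for s in samples})
        drugs = sorted({s[1] for s in samples} | {s[2] for s in samples})
        cpos = {c: k for k, c in enumerate(cells)}
        dpos = {d: k for k, d in enumerate(drugs)}
        ZC = self._encode_cells(dataset, cells)
        ZDa = self._encode_drugs(dataset, drugs)
        ZDb = ZDa if (self.config.share_drug_encoder or not self.config.use_gnn) else self._encode_drugs(dataset, drugs, second=True)
        ci = np.array([cpos[s[0]] for s in samples])
        ai = np.array([dpos[s[1]] for s in samples])
        bi = np.array([dpos[s[2]] for s in samples])
        if swap:
            ai, bi = bi, ai
        return fuse_and_classify(ZC[ci], ZDa[ai], ZDb[bi], self.head)

    def forward_samples_both(self, dataset: AssembledDataset, idx: np.ndarray) -> tuple[Tensor, Tensor]:
        """Log-probabilities in both drug orders, sharing entity encodings."""
        samples = [dataset.samples[i] for i in idx]
        cells = sorted({s[0] for s in samples})
        drugs = sorted({s[1] for s in samples} | {s[2] for s in samples})
        cpos = {c: k for k, c in enumerate(cells)}
        dpos = {d: k for k, d in enumerate(drugs)}
        ZC = self._encode_cells(dataset, cells)
        ZDa = self._encode_drugs(dataset, drugs)
        ZDb = ZDa if (self.config.share_drug_encoder or not self.config.use_gnn) else self._encode_drugs(dataset, drugs, second=True)
        ci = np.array([cpos[s[0]] for s in samples])
        ai = np.array([dpos[s[1]] for s in samples])
        bi = np.array([dpos[s[2]] for s in samples])
        lp1 = fuse_and_classify(ZC[ci], ZDa[ai], ZDb[bi], self.head)
        lp2 = fuse_and_classify(ZC[ci], ZDa[bi], ZDb[ai], self.head)
        return lp1, lp2

    def forward_regression(self, dataset: AssembledDataset, idx: np.ndarray) -> Tensor:
        samples = [dataset.samples[i] for i in idx]
        cells = sorted({s[0] for s in samples})
        drugs = sorted({s[1] for s in samples} | {s[2] for s in samples})
        cpos = {c: k for k, c in enumerate(cells)}
        dpos = {d: k for k, d in enumerate(drugs)}
        ZC = self._encode_cells(dataset, cells)
        ZD = self._encode_drugs(dataset, drugs)
        ci = np.array([cpos[s[0]] for s in samples])
        ai = np.array([dpos[s[1]] for s in samples])
        bi = np.array([dpos[s[2]] for s in samples])
        z = concat([ZC[ci], ZD[ai], ZD[bi]], axis=1)
        return self.head.regress(z)


def _attach_raw_expression(dataset: AssembledDataset, expression=None) -> None:
    """Cache per-cell raw vectors for the DKPE-off branch."""
    if "raw_expression" in dataset.provenance:
        return
    if expression is None:
        raise ValueError(
            "the DKPE-off ablation needs the expression table; pass it via "
            "SynergyModel(..., expression=...)"
        )
    dataset.provenance["raw_expression"] = {
        c: expression.loc[c].to_numpy(dtype=np.float64) for c in dataset.tensors
    }


@dataclass
class SynergyResults:
    """Fit results: trained network, history and evaluation metrics."""

    model: "SynergyModel"
    net: SynergyNet
    history: list[dict]
    report: EvalReport | None
    config: TrainConfig

    def predict_proba(self, dataset: AssembledDataset, idx=None) -> np.ndarray:
        """P(synergistic) per sample, dropout disabled.

        A combination is an unordered pair, so the probability is averaged
        over both drug orders.
        """
        if idx is None:
            idx = np.arange(len(dataset))
        idx = np.asarray(idx)
        self.net.eval()
        lp1, lp2 = self.net.forward_samples_both(dataset, idx)
        return 0.5 * (np.exp(lp1.data[:, 1]) + np.exp(lp2.data[:, 1]))

    def predict_scores(self, dataset: AssembledDataset, idx=None) -> np.ndarray:
        if idx is None:
            idx = np.arange(len(dataset))
        self.net.eval()
        return self.net.forward_regression(dataset, np.asarray(idx)).data

    def evaluate(self, dataset: AssembledDataset, idx=None) -> dict:
        if idx is None:
            idx = np.arange(len(dataset))
        idx = np.asarray(idx)
        p = self.predict_proba(dataset, idx)
        y = dataset.labels[idx]
        kw = {}
        if self.config.regression_head:
            kw = {
                "pred_values": self.predict_scores(dataset, idx),
                "true_values": np.array([dataset.samples[i][4] for i in idx]),
            }
        return metric_suite(p, y, **kw)

    def summary(self) -> str:
        lines = [
            "Synergy classifier fit",
            "=" * 46,
            f"samples: {len(self.model.dataset)}   epochs: {self.config.num_epochs}"
            f"   batch: {self.config.batch_size}",
            f"branches: dkpe={self.config.use_dkpe} gnn={self.config.use_gnn}"
            f" ({self.config.gnn_type}, L={self.config.num_layer}, d={self.config.emb_dim})",
        ]
        if self.history:
            lines.append(
                f"loss: {self.history[0]['train_loss']:.4f} → {self.history[-1]['train_loss']:.4f}"
            )
        if self.report is not None:
            lines.append("-" * 46)
            lines.append(self.report.summary())
        return "\n".join(lines)

    def save(self, path) -> None:
        state = self.net.state_dict()
        meta = {"version": 1, "config": self.config.__dict__.copy()}
        meta["config"]["hidden_sizes"] = list(self.config.hidden_sizes)
        np.savez(path, __meta__=json.dumps(meta), **state)


def load_results(path, dataset: AssembledDataset, expression=None) -> SynergyResults:
    """Rebuild a results object from a saved checkpoint."""
    with np.load(path, allow_pickle=False) as arc:
        meta = json.loads(str(arc["__meta__"]))
        state = {k: arc[k] for k in arc.files if k != "__meta__"}
    if meta.get("version") != 1:
        raise ValueError(f"unsupported checkpoint version: {meta.get('version')}")
    cfg_d = meta["config"]
    cfg_d["hidden_sizes"] = tuple(cfg_d["hidden_sizes"])
    config = TrainConfig(**cfg_d)
    model = SynergyModel(dataset, config, expression=expression)
    net = model._build_net()
    net.load_state_dict(state)
    return SynergyResults(model=model, net=net, history=[], report=None, config=config)


class SynergyModel:
    """Construct from data, then ``fit()``.

    Parameters
    ----------
    dataset : AssembledDataset
        Output of :func:`combosyn.data.assemble_dataset`.
    config : TrainConfig
        Architecture and optimization settings, including the ablation
        flags ``use_dkpe`` / ``use_gnn``.
    expression : DataFrame, optional
        Required only when ``use_dkpe=False`` (the raw-vector baseline
        needs the expression table the tensors were built from).
    """

    def __init__(self, dataset: AssembledDataset, config: TrainConfig | None = None, expression=None):
        self.dataset = dataset
        self.config = config or TrainConfig()
        if not self.config.use_dkpe:
            _attach_raw_expression(dataset, expression)
        if len(dataset) == 0:
            raise ValueError("dataset is empty")
        self._gene_dim = None
        if not self.config.use_dkpe:
            any_cell = next(iter(dataset.provenance["raw_expression"].values()))
            self._gene_dim = len(any_cell)

    def _build_net(self, seed: int | None = None) -> SynergyNet:
        rng = np.random.default_rng(self.config.seed if seed is None else seed)
        return SynergyNet(self.config, self._gene_dim or 0, rng)

    def fit(
        self,
        seed: int | None = None,
        train_idx=None,
        val_idx=None,
        verbose: bool = False,
    ) -> SynergyResults:
        """Train by NLL minimization with Adam; fully seeded.

        ``train_idx``/``val_idx`` restrict training and evaluation to index
        subsets (used by cross-validation); by default the whole dataset
        trains and no held-out report is produced.
        """
        cfg = self.config
        seed = cfg.seed if seed is None else seed
        train_idx = np.arange(len(self.dataset)) if train_idx is None else np.asarray(train_idx)
        y = self.dataset.labels
        if len(np.unique(y[train_idx])) < 2:
            raise ValueError("training set must contain both classes")
        rng = np.random.default_rng(seed)
        net = self._build_net(seed)
        opt = Adam(net.parameters(), lr=cfg.lr)
        history: list[dict] = []
        n = len(train_idx)
        for epoch in range(cfg.num_epochs):
            net.train()
            order = rng.permutation(n)
            epoch_loss = 0.0
            n_batches = 0
            for start in range(0, n, cfg.batch_size):
                batch = train_idx[order[start : start + cfg.batch_size]]
                yy = y[batch]
                if cfg.pair_augment:
                    # pair-order augmentation: every sample in both (A,B) and
                    # (B,A) order; entity encodings are shared between the two
                    lp1, lp2 = net.forward_samples_both(self.dataset, batch)
                    rows = np.arange(len(batch))
                    nll = -0.5 * (lp1[rows, yy].mean() + lp2[rows, yy].mean())
                else:
                    logp = net.forward_samples(self.dataset, batch)
                    nll = -logp[np.arange(len(batch)), yy].mean()
                loss = nll
                if cfg.regression_head:
                    pred = net.forward_regression(self.dataset, batch)
                    truth = np.array([self.dataset.samples[i][4] for i in batch])
                    mse = ((pred - Tensor(truth)) ** 2).mean()
                    loss = loss + 0.01 * mse  # scores are O(10): keep NLL dominant
                opt.zero_grad()
                loss.backward()
                opt.step()
                epoch_loss += float(nll.data)
                n_batches += 1
            entry = {"epoch": epoch, "train_loss": epoch_loss / max(n_batches, 1)}
            history.append(entry)
            if verbose:
                print(json.dumps(entry))
        results = SynergyResults(model=self, net=net, history=history, report=None, config=cfg)
        if val_idx is not None:
            m = results.evaluate(self.dataset, val_idx)
            results.report = EvalReport(
                auc=m["auc"], aupr=m["aupr"], acc=m["acc"],
                pcc=m.get("pcc", float("nan")), rmse=m.get("rmse", float("nan")),
                per_fold=[m], n_folds=1,
            )
        return results


def stratified_folds(labels, k: int, seed: int = 0) -> list[np.ndarray]:
    """Seeded stratified partition into k folds.

    Shuffled indices of each class are dealt round-robin, with the dealing
    rotation carried across classes so overall fold sizes are balanced to
    ±1 while each class stays balanced to ±1 per fold.
    """
    labels = np.asarray(labels)
    n = len(labels)
    if n < k:
        raise ValueError(f"need at least k={k} samples, got {n}")
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    cursor = 0
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        for i in idx:
            folds[cursor % k].append(int(i))
            cursor += 1
    return [np.array(sorted(f), dtype=int) for f in folds]


def cross_validate(
    dataset: AssembledDataset,
    config: TrainConfig | None = None,
    k: int = 5,
    seed: int = 0,
    expression=None,
) -> EvalReport:
    """Stratified k-fold protocol: every sample validates exactly once."""
    config = config or TrainConfig()
    model = SynergyModel(dataset, config, expression=expression)
    folds = stratified_folds(dataset.labels, k, seed)
    per_fold = []
    for f, val_idx in enumerate(folds):
        train_idx = np.setdiff1d(np.arange(len(dataset)), val_idx)
        res = model.fit(seed=seed + f, train_idx=train_idx, val_idx=val_idx)
        per_fold.append(res.report.per_fold[0])
    pccs = [m["pcc"] for m in per_fold if "pcc" in m]
    rmses = [m["rmse"] for m in per_fold if "rmse" in m]
    return EvalReport(
        auc=float(np.mean([m["auc"] for m in per_fold])),
        aupr=float(np.mean([m["aupr"] for m in per_fold])),
        acc=float(np.mean([m["acc"] for m in per_fold])),
        pcc=float(np.nanmean(pccs)) if pccs else float("nan"),
        rmse=float(np.nanmean(rmses)) if rmses else float("nan"),
        per_fold=per_fold,
        n_folds=k,
    )


ABLATION_VARIANTS = (
    ("complete", True, True),
    ("dkpe_only", True, False),
    ("gnn_only", False, True),
    ("neither", False, False),
)


def run_ablation(
    dataset: AssembledDataset,
    config: TrainConfig | None = None,
    k: int = 3,
    seed: int = 0,
    expression=None,
) -> dict[str, EvalReport]:
    """Train the four branch-ablation variants under identical folds/seeds."""
    config = config or TrainConfig()
    out: dict[str, EvalReport] = {}
    for name, use_dkpe, use_gnn in ABLATION_VARIANTS:
        variant = replace(config, use_dkpe=use_dkpe, use_gnn=use_gnn)
        report = cross_validate(dataset, variant, k=k, seed=seed, expression=expression)
        report.ablation = {"use_dkpe": use_dkpe, "use_gnn": use_gnn}
        out[name] = report
    return out
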