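"""A linear-chain conditional random field with an sklearn-style surface.

The model scores a tag sequence :math:`y` for a token sequence with
feature rows :math:`x` as

.. math::

    s(x, y) = \\sum_t w_{\\mathrm{emit}}[f(x_t), y_t]
             + \\sum_t w_{\\mathrm{trans}}[y_{t-1}, y_t]
             + w_{\\mathrm{start}}[y_1] + w_{\\mathrm{end}}[y_T]

and is trained by maximizing the conditional log-likelihood with an L2
penalty ``c2 * ||w||^2`` using L-BFGS.  Inference is exact (Viterbi);
the partition function and feature expectations come from the
forward–backward recursions, run in log space and batched over all
sequences at once so training stays fast in pure NumPy.

Inputs mirror the conventional CRF-tagger surface: ``X`` is a list of
sequences, each a list of ``{feature name: value}`` dicts; ``y`` is a
list of equal-length tag lists.  Features are treated as categorical
indicators ``name=value``.  Training is deterministic given the input
order and configuration.
"""

from __future__ import annotations

import hashlib
import warnings

import numpy as np
import scipy.optimize
import scipy.sparse as sp
from scipy.special import logsumexp
from sklearn.base import BaseEstimator


class SchemaMismatchError(ValueError):
    """Prediction input has a different feature schema than training."""


def schema_of(X) -> tuple[str, ...]:
    """The sorted set of base feature names appearing in a feature table."""
    names: set[str] = set()
    for seq in X:
        for row in seq:
            names.update(row.keys())
    return tuple(sorted(names))


def schema_hash(schema: tuple[str, ...]) -> str:
    return hashlib.sha256("\x00".join(schema).encode("utf-8")).hexdigest()


class ChainCRF(BaseEstimator):
    """Linear-chain CRF sequence labeler.

    Parameters
    ----------
    c2 : float
        L2 regularization weight (penalty ``c2 * ||w||^2``).
    max_iterations : int
        L-BFGS iteration cap.
    tol : float
        Relative objective-decrease stopping tolerance (L-BFGS ``ftol``).
    check_schema : bool
        If True (default), ``predict`` rejects inputs whose feature-name
        schema differs from the one seen at ``fit`` time.

    Attributes
    ----------
    classes_ : list of tag names (sorted).
    feature_index_ : dict mapping ``name=value`` strings to columns.
    coef_emit_, coef_trans_, coef_start_, coef_end_ : learned weights.
    schema_ / schema_hash_ : feature-name schema captured at fit time.
    n_iter_ : L-BFGS iterations performed.
    """

    def __init__(
        self,
        c2: float = 1.0,
        max_iterations: int = 100,
        tol: float = 1e-6,
        check_schema: bool = True,
    ):
        self.c2 = c2
        self.max_iterations = max_iterations
        self.tol = tol
        self.check_schema = check_schema

    # -- encoding ----------------------------------------------------------

    @staticmethod
    def _row_features(row: dict) -> list[str]:
        return [f"{k}={v}" for k, v in row.items()]

    def _build_matrix(self, X, fit_vocab: bool):
        """CSR indicator matrix over all tokens plus sequence lengths."""
        if fit_vocab:
            vocab: dict[str, int] = {}
        else:
            vocab = self.feature_index_
        indptr = [0]
        indices: list[int] = []
        lengths = []
        for seq in X:
            for row in seq:
                for feat in self._row_features(row):
                    if fit_vocab:
                        col = vocab.setdefault(feat, len(vocab))
                        indices.append(col)
                    else:
                        col = vocab.get(feat)
                        if col is not None:
                            indices.append(col)
                indptr.append(len(indices))
            lengths.append(len(seq))
        if fit_vocab:
            self.feature_index_ = vocab
        n_feat = len(vocab)
        mat = sp.csr_matrix(
            (
                np.ones(len(indices), dtype=np.float64),
                np.asarray(indices, dtype=np.int64),
                np.asarray(indptr, dtype=np.int64),
            ),
            shape=(len(indptr) - 1, n_feat),
        )
        return mat, np.asarray(lengths, dtype=np.int64)

    def _pack(self, values: np.ndarray, lengths: np.ndarray) -> np.ndarray:
        """(N_tokens, L) -> padded (S, T_max, L); padding rows are zero."""
        S = len(lengths)
        T = int(lengths.max()) if S else 0
        L = values.shape[1]
        out = np.zeros((S, T, L))
        offset = 0
        for s, n in enumerate(lengths):
            out[s, :n] = values[offset : offset + n]
            offset += n
        return out

    # -- training ----------------------------------------------------------

    def fit(self, X, y):
        X = list(X)
        y = list(y)
        if not X or sum(len(s) for s in X) == 0:
            raise ValueError("cannot fit a CRF on an empty corpus")
        if len(X) != len(y) or any(len(a) != len(b) for a, b in zip(X, y)):
            raise ValueError("X and y must align sequence by sequence")
        # drop zero-length sequences (nothing to tag)
        pairs = [(a, b) for a, b in zip(X, y) if len(a) > 0]
        X = [a for a, _ in pairs]
        y = [b for _, b in pairs]

        labels = sorted({tag for seq in y for tag in seq})
        if len(labels) < 2:
            warnings.warn(
                "training corpus contains a single tag class; the model is degenerate",
                stacklevel=2,
            )
        self.classes_ = labels
        self.schema_ = schema_of(X)
        self.schema_hash_ = schema_hash(self.schema_)

        mat, lengths = self._build_matrix(X, fit_vocab=True)
        L = len(labels)
        label_idx = {lab: i for i, lab in enumerate(labels)}
        y_flat = np.asarray(
            [label_idx[tag] for seq in y for tag in seq], dtype=np.int64
        )

        S = len(lengths)
        T = int(lengths.max())
        F = mat.shape[1]
        pos = np.arange(T)
        valid = pos[None, :] < lengths[:, None]  # (S, T)
        is_last = pos[None, :] == (lengths - 1)[:, None]

        # indices to scatter packed (S, T) arrays back to flat token order
        seq_ids = np.repeat(np.arange(S), lengths)
        pos_ids = np.concatenate([np.arange(n) for n in lengths])

        # empirical sufficient statistics
        y_onehot = np.zeros((y_flat.size, L))
        y_onehot[np.arange(y_flat.size), y_flat] = 1.0
        emp_emit = mat.T @ y_onehot  # (F, L)
        y_packed = np.full((S, T), -1, dtype=np.int64)
        y_packed[seq_ids, pos_ids] = y_flat
        emp_trans = np.zeros((L, L))
        prev = y_packed[:, :-1]
        nxt = y_packed[:, 1:]
        pair_valid = valid[:, 1:]
        np.add.at(emp_trans, (prev[pair_valid], nxt[pair_valid]), 1.0)
        emp_start = np.bincount(y_packed[:, 0], minlength=L).astype(float)
        emp_end = np.bincount(
            y_packed[np.arange(S), lengths - 1], minlength=L
        ).astype(float)

        n_emit = F * L

        def unpack(w):
            w_emit = w[:n_emit].reshape(F, L)
            w_trans = w[n_emit : n_emit + L * L].reshape(L, L)
            w_start = w[n_emit + L * L : n_emit + L * L + L]
            w_end = w[n_emit + L * L + L :]
            return w_emit, w_trans, w_start, w_end

        def objective(w):
            w_emit, w_trans, w_start, w_end = unpack(w)
            emis_flat = mat @ w_emit  # (N, L)
            emis = self._pack(emis_flat, lengths)  # (S, T, L)

            # forward, frozen past each sequence's end
            alpha = np.zeros((S, T, L))
            alpha[:, 0] = w_start + emis[:, 0]
            for t in range(1, T):
                cont = (
                    logsumexp(
                        alpha[:, t - 1, :, None] + w_trans[None, :, :], axis=1
                    )
                    + emis[:, t]
                )
                alpha[:, t] = np.where(valid[:, t, None], cont, alpha[:, t - 1])
            log_z = logsumexp(alpha[:, T - 1] + w_end[None, :], axis=1)  # (S,)

            # backward
            beta = np.zeros((S, T, L))
            beta[:, T - 1] = w_end
            for t in range(T - 2, -1, -1):
                cont = logsumexp(
                    w_trans[None, :, :]
                    + (emis[:, t + 1] + beta[:, t + 1])[:, None, :],
                    axis=2,
                )
                beta[:, t] = np.where(is_last[:, t, None], w_end, cont)

            # unary marginals
            log_p = alpha + beta - log_z[:, None, None]
            p = np.exp(log_p)
            p[~valid] = 0.0
            p_flat = p[seq_ids, pos_ids]  # (N, L)

            # pairwise expectations
            log_pair = (
                alpha[:, :-1, :, None]
                + w_trans[None, None, :, :]
                + (emis[:, 1:] + beta[:, 1:])[:, :, None, :]
                - log_z[:, None, None, None]
            )
            pair = np.exp(log_pair)
            pair[~pair_valid] = 0.0
            e_trans = pair.sum(axis=(0, 1))

            # gold-path score
            gold = (
                (emis_flat * y_onehot).sum()
                + (emp_trans * w_trans).sum()
                + (emp_start * w_start).sum()
                + (emp_end * w_end).sum()
            )
            nll = log_z.sum() - gold + self.c2 * (w @ w)

            g_emit = (mat.T @ p_flat) - emp_emit
            g_trans = e_trans - emp_trans
            g_start = p[:, 0].sum(axis=0) - emp_start
            g_end = p[np.arange(S), lengths - 1].sum(axis=0) - emp_end
            grad = np.concatenate(
                [g_emit.ravel(), g_trans.ravel(), g_start, g_end]
            ) + 2.0 * self.c2 * w
            return nll, grad

        w0 = np.zeros(n_emit + L * L + 2 * L)
        result = scipy.optimize.minimize(
            objective,
            w0,
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": self.max_iterations, "ftol": self.tol},
        )
        w_emit, w_trans, w_start, w_end = unpack(result.x)
        self.coef_emit_ = w_emit
        self.coef_trans_ = w_trans
        self.coef_start_ = w_start
        self.coef_end_ = w_end
        self.n_iter_ = int(result.nit)
        self.final_loss_ = float(result.fun)
        return self

    # -- inference ---------------------------------------------------------

    def _check_fitted(self):
        if not hasattr(self, "coef_emit_"):
            raise RuntimeError("ChainCRF is not fitted")

    def predict(self, X) -> list[list[str]]:
        """Viterbi-decode the most probable tag sequence per sentence."""
        self._check_fitted()
        X = list(X)
        if self.check_schema:
            incoming = schema_of(X)
            if incoming and incoming != self.schema_:
                missing = set(self.schema_) - set(incoming)
                extra = set(incoming) - set(self.schema_)
                raise SchemaMismatchError(
                    f"feature schema differs from training "
                    f"(missing={sorted(missing)[:5]}, extra={sorted(extra)[:5]})"
                )
        mat, lengths = self._build_matrix(X, fit_vocab=False)
        emis_flat = mat @ self.coef_emit_
        out: list[list[str]] = []
        offset = 0
        for n in lengths:
            emis = emis_flat[offset : offset + n]
            offset += n
            out.append(self._viterbi(emis))
        return out

    def _viterbi(self, emis: np.ndarray) -> list[str]:
        n, L = emis.shape
        if n == 0:
            return []
        delta = self.coef_start_ + emis[0]
        back = np.zeros((n, L), dtype=np.int64)
        for t in range(1, n):
            scores = delta[:, None] + self.coef_trans_
            back[t] = scores.argmax(axis=0)
            delta = scores.max(axis=0) + emis[t]
        delta = delta + self.coef_end_
        path = [int(delta.argmax())]
        for t in range(n - 1, 0, -1):
            path.append(int(back[t, path[-1]]))
        path.reverse()
        return [self.classes_[i] for i in path]
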