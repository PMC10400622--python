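"""Per-chain feature tables, interface labels, and pair records.

A chain's features live in a pandas DataFrame with one row per standard
residue, vector features expanded into fixed-width column groups
(``pi_0..pi_5``, ``hsaac_0..hsaac_41``, ``profile_0..profile_26``,
``nv_x..nv_z``, ``ca_x..ca_z``).  Two such tables plus positive and
negative inter-chain residue-pair index lists form a
:class:`PairRecord`, serialized to HDF5 (column datasets under
``/table_0`` and ``/table_1``, ``N x 2`` label arrays under ``/labels``,
run metadata as ``/meta`` attributes) or to a pickle file.

Positives are inter-chain residue pairs whose minimum heavy-atom
distance falls under the contact threshold (6 Å by default); a
``ca_only`` mode measures CA-CA distances instead.  Negatives are an
equally-sized uniform sample, without replacement, from the remaining
pairs, drawn from the lexicographically sorted candidate list with a
seeded generator so results are platform-independent.
"""

from __future__ import annotations

import json
import pickle
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .structure import Chain

__all__ = [
    "KEY_COLS",
    "SCALAR_FEATURE_COLS",
    "PI_COLS",
    "HSAAC_COLS",
    "PROFILE_COLS",
    "NV_COLS",
    "CA_COLS",
    "NUMERIC_FEATURE_COLS",
    "build_feature_table",
    "find_positive_pairs",
    "sample_negatives",
    "impute_missing",
    "PairRecord",
]

KEY_COLS = ["chain_id", "resseq", "icode", "resname"]
PI_COLS = [f"pi_{i}" for i in range(6)]
HSAAC_COLS = [f"hsaac_{i}" for i in range(42)]
PROFILE_COLS = [f"profile_{i}" for i in range(27)]
NV_COLS = ["nv_x", "nv_y", "nv_z"]
CA_COLS = ["ca_x", "ca_y", "ca_z"]
SCALAR_FEATURE_COLS = ["rsa", "rd_norm", "cn_norm", "idr_propensity", "idr_flag"]
#: Numeric columns subject to imputation (coordinates and keys excluded).
NUMERIC_FEATURE_COLS = (
    SCALAR_FEATURE_COLS + PI_COLS + HSAAC_COLS + PROFILE_COLS + NV_COLS
)


def _as_2d(name: str, values, n: int, width: int) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.shape != (n, width):
        raise ValueError(
            f"feature {name!r} has shape {arr.shape}, expected ({n}, {width})"
        )
    return arr


def build_feature_table(
    chain: Chain,
    *,
    rsa,
    rd_norm,
    cn_norm,
    pi,
    hsaac,
    profile,
    nv,
    ca_coords,
    ss=None,
    idr_propensity=None,
    idr_flag=None,
) -> pd.DataFrame:
    """Assemble one feature row per standard residue, in chain order.

    Scalar features are 1-D arrays, vector features 2-D arrays of the
    documented widths (6/42/27/3/3).  Secondary structure defaults to
    the unknown symbol '-'; disorder annotations default to NaN.  Any
    length mismatch raises ValueError.
    """
    residues = [r for r in chain.residues if r.is_standard_aa]
    n = len(residues)
    scalars = {"rsa": rsa, "rd_norm": rd_norm, "cn_norm": cn_norm}
    for name, values in scalars.items():
        scalars[name] = np.asarray(values, dtype=float)
        if scalars[name].shape != (n,):
            raise ValueError(
                f"feature {name!r} has length {scalars[name].shape}, expected {n}"
            )
    pi = _as_2d("pi", pi, n, 6)
    hsaac = _as_2d("hsaac", hsaac, n, 42)
    profile = _as_2d("profile", profile, n, 27)
    nv = _as_2d("nv", nv, n, 3)
    ca_coords = _as_2d("ca_coords", ca_coords, n, 3)
    if ss is None:
        ss = ["-"] * n
    elif len(ss) != n:
        raise ValueError(f"ss has length {len(ss)}, expected {n}")
    idr_propensity = (
        np.full(n, np.nan) if idr_propensity is None
        else np.asarray(idr_propensity, dtype=float)
    )
    idr_flag = (
        np.full(n, np.nan) if idr_flag is None
        else np.asarray(idr_flag, dtype=float)
    )
    if idr_propensity.shape != (n,) or idr_flag.shape != (n,):
        raise ValueError("disorder annotations must have one value per residue")

    data: dict[str, object] = {
        "chain_id": [r.chain_id for r in residues],
        "resseq": [r.resseq for r in residues],
        "icode": [r.icode for r in residues],
        "resname": [r.name3 for r in residues],
        "ss": list(ss),
        "rsa": scalars["rsa"],
        "rd_norm": scalars["rd_norm"],
        "cn_norm": scalars["cn_norm"],
        "idr_propensity": idr_propensity,
        "idr_flag": idr_flag,
    }
    for cols, arr in [
        (PI_COLS, pi),
        (HSAAC_COLS, hsaac),
        (PROFILE_COLS, profile),
        (NV_COLS, nv),
        (CA_COLS, ca_coords),
    ]:
        for k, col in enumerate(cols):
            data[col] = arr[:, k]
    return pd.DataFrame(data)


def _residue_coords(chain: Chain, mode: str) -> tuple[np.ndarray, np.ndarray]:
    """Stacked heavy-atom (or CA) coordinates with their residue row index."""
    coords, owner = [], []
    residues = [r for r in chain.residues if r.is_standard_aa]
    for row, res in enumerate(residues):
        if mode == "ca_only":
            ca = res.get_atom("CA")
            if ca is not None:
                coords.append(ca.coords)
                owner.append(row)
        else:
            for atom in res.heavy_atoms():
                coords.append(atom.coords)
                owner.append(row)
    if not coords:
        return np.empty((0, 3)), np.empty(0, dtype=int)
    return np.array(coords), np.array(owner, dtype=int)


def find_positive_pairs(
    chain_a: Chain,
    chain_b: Chain,
    threshold: float = 6.0,
    mode: str = "heavy_atom",
    inclusive: bool = False,
) -> np.ndarray:
    """Inter-chain residue pairs within the contact threshold.

    Returns an (N, 2) array of 0-based row indices into the two chains'
    feature tables, sorted lexicographically.  ``mode='heavy_atom'``
    (default) uses the minimum non-hydrogen atom distance;
    ``mode='ca_only'`` the CA-CA distance.  The boundary is strict
    (< threshold) unless ``inclusive``.
    """
    if mode not in {"heavy_atom", "ca_only"}:
        raise ValueError(f"unknown contact mode {mode!r}")
    ca_coords, ca_owner = _residue_coords(chain_a, mode)
    cb_coords, cb_owner = _residue_coords(chain_b, mode)
    if len(ca_coords) == 0 or len(cb_coords) == 0:
        return np.empty((0, 2), dtype=int)
    n0 = int(ca_owner.max()) + 1
    n1 = int(cb_owner.max()) + 1
    dmin = np.full((n0, n1), np.inf)
    d = cdist(ca_coords, cb_coords)
    np.minimum.at(dmin, (ca_owner[:, None], cb_owner[None, :]), d)
    hit = dmin <= threshold if inclusive else dmin < threshold
    rows, cols = np.nonzero(hit)
    pairs = np.column_stack([rows, cols]).astype(int)
    order = np.lexsort((pairs[:, 1], pairs[:, 0]))
    return pairs[order]


def sample_negatives(
    positives: np.ndarray,
    n0: int,
    n1: int,
    seed: int,
) -> np.ndarray:
    """Uniform, seeded sample of non-interacting residue pairs.

    The sample has size ``min(len(positives), candidates)`` where the
    candidate set is all ``n0 x n1`` inter-chain pairs minus the
    positives; it is drawn without replacement and returned sorted
    lexicographically.  Fewer candidates than positives yields all
    candidates plus a warning.
    """
    positives = np.asarray(positives, dtype=int).reshape(-1, 2)
    total = n0 * n1
    pos_flat = positives[:, 0] * n1 + positives[:, 1] if len(positives) else []
    candidates = np.setdiff1d(np.arange(total), pos_flat)  # sorted
    size = min(len(positives), len(candidates))
    if size < len(positives):
        warnings.warn(
            f"only {len(candidates)} non-interacting pairs available for "
            f"{len(positives)} positives; taking all of them",
            stacklevel=2,
        )
    if size == 0:
        return np.empty((0, 2), dtype=int)
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(candidates), size=size, replace=False)
    flat = np.sort(candidates[chosen])
    return np.column_stack([flat // n1, flat % n1]).astype(int)


_STRATEGIES = {
    "median": np.nanmedian,
    "mean": np.nanmean,
    "min": np.nanmin,
    "max": np.nanmax,
}


def impute_missing(
    table: pd.DataFrame,
    strategy: str = "median",
    constant: float = 0.0,
    columns: list[str] | None = None,
) -> pd.DataFrame:
    """Fill NaNs in numeric feature columns, columnwise.

    ``strategy`` is one of median / mean / min / max / constant.  A
    column that is entirely NaN falls back to the constant (default 0)
    with a warning.  Non-NaN values and non-numeric columns (e.g. the
    categorical ``ss``) are untouched; vector features are imputed
    element-wise since each element is its own column.
    """
    if strategy != "constant" and strategy not in _STRATEGIES:
        raise ValueError(f"unknown imputation strategy {strategy!r}")
    out = table.copy()
    if columns is None:
        columns = [
            c for c in out.columns
            if c in NUMERIC_FEATURE_COLS and pd.api.types.is_numeric_dtype(out[c])
        ]
    for col in columns:
        values = out[col].to_numpy(dtype=float)
        mask = np.isnan(values)
        if not mask.any():
            continue
        if strategy == "constant":
            fill = constant
        elif mask.all():
            warnings.warn(
                f"column {col!r} is entirely NaN; filling with constant {constant}",
                stacklevel=2,
            )
            fill = constant
        else:
            fill = float(_STRATEGIES[strategy](values))
        values[mask] = fill
        out[col] = values
    return out


@dataclass
class PairRecord:
    """A binary complex: two feature tables plus interface labels."""

    pdb_id: str
    chain_ids: tuple[str, str]
    pair_index: int
    table_0: pd.DataFrame
    table_1: pd.DataFrame
    positives: np.ndarray
    negatives: np.ndarray
    assembly: int = 1
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positives = np.asarray(self.positives, dtype=int).reshape(-1, 2)
        self.negatives = np.asarray(self.negatives, dtype=int).reshape(-1, 2)
        pos = {tuple(p) for p in self.positives}
        neg = {tuple(p) for p in self.negatives}
        if pos & neg:
            raise ValueError("positives and negatives overlap")
        for arr, name in [(self.positives, "positives"), (self.negatives, "negatives")]:
            if len(arr) and (
                arr[:, 0].max() >= len(self.table_0)
                or arr[:, 1].max() >= len(self.table_1)
                or arr.min() < 0
            ):
                raise ValueError(f"{name} reference rows outside the tables")

    @property
    def name(self) -> str:
        return f"{self.pdb_id}.pdb{self.assembly}_{self.pair_index}"

    @property
    def bucket(self) -> str:
        """Directory bucket: 2nd+3rd characters of the PDB id."""
        return self.pdb_id[1:3]

    # --- serialization -------------------------------------------------

    def to_hdf5(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with h5py.File(path, "w") as f:
            for idx, table in [(0, self.table_0), (1, self.table_1)]:
                grp = f.create_group(f"table_{idx}")
                grp.attrs["columns"] = json.dumps(list(table.columns))
                for col in table.columns:
                    values = table[col].to_numpy()
                    if values.dtype == object:
                        values = values.astype("S")
                    grp.create_dataset(col, data=values, track_times=False)
            labels = f.create_group("labels")
            labels.create_dataset("positives", data=self.positives, track_times=False)
            labels.create_dataset("negatives", data=self.negatives, track_times=False)
            meta = f.create_group("meta")
            meta.attrs["pdb_id"] = self.pdb_id
            meta.attrs["chain_ids"] = json.dumps(list(self.chain_ids))
            meta.attrs["pair_index"] = self.pair_index
            meta.attrs["assembly"] = self.assembly
            meta.attrs["metadata"] = json.dumps(self.metadata, sort_keys=True)
        return path

    @classmethod
    def from_hdf5(cls, path: str | Path) -> "PairRecord":
        with h5py.File(path, "r") as f:
            tables = []
            for idx in (0, 1):
                grp = f[f"table_{idx}"]
                columns = json.loads(grp.attrs["columns"])
                data = {}
                for col in columns:
                    values = grp[col][()]
                    if values.dtype.kind == "S":
                        values = values.astype(str)
                    data[col] = values
                tables.append(pd.DataFrame(data))
            meta = f["meta"]
            return cls(
                pdb_id=str(meta.attrs["pdb_id"]),
                chain_ids=tuple(json.loads(meta.attrs["chain_ids"])),
                pair_index=int(meta.attrs["pair_index"]),
                table_0=tables[0],
                table_1=tables[1],
                positives=f["labels/positives"][()],
                negatives=f["labels/negatives"][()],
                assembly=int(meta.attrs["assembly"]),
                metadata=json.loads(meta.attrs["metadata"]),
            )

    def to_pickle(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "wb") as f:
            pickle.dump(self, f)
        return path

    @classmethod
    def from_pickle(cls, path: str | Path) -> "PairRecord":
        with open(path, "rb") as f:
            record = pickle.load(f)
        if not isinstance(record, cls):
            raise TypeError(f"{path} does not contain a PairRecord")
        return record
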