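"""Packed, presynaptic-indexed connection storage and the per-tile file.

Each connection is a fixed 14-byte record — postsynaptic gid (4-byte
unsigned), weight (IEEE-754 single), delay in integration-step ticks
(2-byte unsigned), synapse type (2-byte unsigned), a reserved plasticity
byte and a local synapse id byte — packed little-endian without padding.
Records are grouped by presynaptic neuron so that delivering one spike is
a single contiguous scan of that neuron's outgoing targets
(struct-of-arrays layout).

The intermediate tile file is a self-describing binary container: magic,
schema version, a JSON metadata block (tile geometry, gid range, config
digest), the neuron arrays, and the packed record block whose size on
disk is exactly 14 × n_records.  A SHA-256 digest over the payload guards
against truncation.
"""

from __future__ import annotations

import hashlib
import json
import struct
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, NamedTuple

import numpy as np

from .builder import ConnectionBatch, TilePopulation

__all__ = [
    "RECORD_STRUCT",
    "RECORD_BYTES",
    "ConnectionRecord",
    "pack_record",
    "unpack_record",
    "ConnectionStore",
    "build_store",
    "FormatError",
    "IntegrityError",
    "write_tile_file",
    "read_tile_file",
]

RECORD_STRUCT = struct.Struct("<IfHHBB")
RECORD_BYTES = RECORD_STRUCT.size
assert RECORD_BYTES == 14

_MAGIC = b"TSTL"
_VERSION = 1


class FormatError(ValueError):
    """The file is not a tile file, or its schema version is unsupported."""


class IntegrityError(ValueError):
    """The file is truncated or its payload digest does not match."""


class ConnectionRecord(NamedTuple):
    """One synapse as stored on the postsynaptic tile."""

    post_gid: int
    weight: float
    delay: int  # integration-step ticks
    syn_type: int
    plasticity_type: int = 0  # reserved
    local_id: int = 0


def pack_record(r: ConnectionRecord) -> bytes:
    """Serialize one record to its 14-byte little-endian layout."""
    if r.delay < 0:
        raise ValueError(f"delay must be >= 0, got {r.delay}")
    if r.delay > 0xFFFF:
        raise OverflowError(f"delay {r.delay} exceeds 2-byte range")
    if not np.isfinite(r.weight):
        raise ValueError("weight must be finite")
    return RECORD_STRUCT.pack(r.post_gid, r.weight, r.delay, r.syn_type,
                              r.plasticity_type, r.local_id)


def unpack_record(buf: bytes) -> ConnectionRecord:
    if len(buf) != RECORD_BYTES:
        raise ValueError(f"expected {RECORD_BYTES} bytes, got {len(buf)}")
    return ConnectionRecord(*RECORD_STRUCT.unpack(buf))


class ConnectionStore:
    """Outgoing-connection lookup indexed by presynaptic gid.

    Internally a single struct-of-arrays block sorted by presynaptic gid,
    with an offset table per presynaptic neuron; `targets_of` is an O(1)
    dict lookup returning array views in insertion order.
    """

    def __init__(self, pre_gids: np.ndarray, offsets: np.ndarray,
                 post_gid: np.ndarray, weight: np.ndarray, delay: np.ndarray,
                 syn_type: np.ndarray, plasticity: np.ndarray,
                 local_id: np.ndarray):
        self._pre_gids = pre_gids  # unique pre gids, ascending
        self._offsets = offsets  # len(pre_gids)+1 prefix offsets into arrays
        self.post_gid = post_gid
        self.weight = weight
        self.delay = delay
        self.syn_type = syn_type
        self.plasticity = plasticity
        self.local_id = local_id
        self._index = {int(g): i for i, g in enumerate(pre_gids)}

    @property
    def n_records(self) -> int:
        return len(self.post_gid)

    @property
    def nbytes(self) -> int:
        """Byte footprint of the packed record payload (14 per record)."""
        return RECORD_BYTES * self.n_records

    @property
    def pre_gids(self) -> np.ndarray:
        return self._pre_gids

    def targets_of(self, pre_gid: int):
        """(post_gids, weights, delays, syn_types) views for one presynaptic gid."""
        i = self._index.get(int(pre_gid))
        if i is None:
            sl = slice(0, 0)
        else:
            sl = slice(self._offsets[i], self._offsets[i + 1])
        return self.post_gid[sl], self.weight[sl], self.delay[sl], self.syn_type[sl]

    def min_delay_ticks(self) -> int | None:
        return int(self.delay.min()) if self.n_records else None

    def records_of(self, pre_gid: int) -> list[ConnectionRecord]:
        post, w, d, s = self.targets_of(pre_gid)
        i = self._index.get(int(pre_gid))
        if i is None:
            return []
        sl = slice(self._offsets[i], self._offsets[i + 1])
        return [
            ConnectionRecord(int(p), float(wt), int(dl), int(st), int(pt), int(li))
            for p, wt, dl, st, pt, li in zip(
                post, w, d, s, self.plasticity[sl], self.local_id[sl])
        ]


def build_store(batch: ConnectionBatch | Iterable[tuple[int, ConnectionRecord]]
                ) -> ConnectionStore:
    """Group a connection batch by presynaptic gid into a `ConnectionStore`.

    Accepts either a `ConnectionBatch` or an iterable of
    ``(pre_gid, ConnectionRecord)`` pairs.  Within one presynaptic neuron
    the insertion order of the batch is preserved.
    """
    if not isinstance(batch, ConnectionBatch):
        rows = list(batch)
        if rows:
            pre = np.array([g for g, _ in rows], dtype=np.int64)
            batch = ConnectionBatch(
                pre_gid=pre,
                post_gid=np.array([r.post_gid for _, r in rows], dtype=np.int64),
                weight=np.array([r.weight for _, r in rows], dtype=np.float32),
                delay_ticks=np.array([r.delay for _, r in rows], dtype=np.uint16),
                syn_type=np.array([r.syn_type for _, r in rows], dtype=np.uint16),
            )
        else:
            batch = ConnectionBatch.empty()
    order = np.argsort(batch.pre_gid, kind="stable")
    pre = batch.pre_gid[order]
    uniq, starts = np.unique(pre, return_index=True)
    offsets = np.empty(len(uniq) + 1, dtype=np.int64)
    offsets[:-1] = starts
    offsets[-1] = len(pre)
    n = len(pre)
    return ConnectionStore(
        pre_gids=uniq,
        offsets=offsets,
        post_gid=batch.post_gid[order].astype(np.uint32),
        weight=batch.weight[order].astype(np.float32),
        delay=batch.delay_ticks[order].astype(np.uint16),
        syn_type=batch.syn_type[order].astype(np.uint16),
        plasticity=np.zeros(n, dtype=np.uint8),
        local_id=np.zeros(n, dtype=np.uint8),
    )


def _packed_payload(store: ConnectionStore) -> bytes:
    """Concatenated 14-byte records, grouped by presynaptic gid."""
    n = store.n_records
    rec = np.zeros(n, dtype=np.dtype(
        [("post", "<u4"), ("w", "<f4"), ("delay", "<u2"), ("syn", "<u2"),
         ("plast", "u1"), ("local", "u1")]))
    rec["post"] = store.post_gid
    rec["w"] = store.weight
    rec["delay"] = store.delay
    rec["syn"] = store.syn_type
    rec["plast"] = store.plasticity
    rec["local"] = store.local_id
    assert rec.itemsize == RECORD_BYTES
    return rec.tobytes()


def _store_from_payload(pre_gids: np.ndarray, counts: np.ndarray,
                        payload: bytes) -> ConnectionStore:
    rec = np.frombuffer(payload, dtype=np.dtype(
        [("post", "<u4"), ("w", "<f4"), ("delay", "<u2"), ("syn", "<u2"),
         ("plast", "u1"), ("local", "u1")]))
    offsets = np.zeros(len(pre_gids) + 1, dtype=np.int64)
    np.cumsum(counts, out=offsets[1:])
    return ConnectionStore(
        pre_gids=pre_gids.astype(np.int64), offsets=offsets,
        post_gid=rec["post"].copy(), weight=rec["w"].copy(),
        delay=rec["delay"].copy(), syn_type=rec["syn"].copy(),
        plasticity=rec["plast"].copy(), local_id=rec["local"].copy(),
    )


def write_tile_file(store: ConnectionStore, pop: TilePopulation,
                    config_digest: str, path: str | Path) -> None:
    """Write one tile's population and connections to a binary container."""
    meta = {
        "tile_id": pop.tile_id,
        "x0": pop.x0, "y0": pop.y0, "tile_len": pop.tile_len,
        "gid_start": pop.gid_start, "n_neurons": pop.n,
        "n_pre": int(len(store.pre_gids)), "n_records": store.n_records,
        "config_digest": config_digest,
    }
    meta_b = json.dumps(meta, sort_keys=True).encode("utf-8")
    blocks = [
        pop.type_index.astype("<u2").tobytes(),
        pop.x.astype("<f8").tobytes(), pop.y.astype("<f8").tobytes(),
        pop.z.astype("<f8").tobytes(), pop.bias.astype("<f8").tobytes(),
        store.pre_gids.astype("<i8").tobytes(),
        np.diff(store._offsets).astype("<i8").tobytes(),
        _packed_payload(store),
    ]
    payload = meta_b + b"".join(blocks)
    digest = hashlib.sha256(payload).digest()
    with open(path, "wb") as fh:
        fh.write(_MAGIC)
        fh.write(struct.pack("<HI", _VERSION, len(meta_b)))
        fh.write(digest)
        fh.write(payload)


def read_tile_file(path: str | Path) -> tuple[ConnectionStore, TilePopulation, str]:
    """Read a tile file back; returns (store, population, config_digest)."""
    raw = Path(path).read_bytes()
    if len(raw) < 4 + 6 + 32 or raw[:4] != _MAGIC:
        raise FormatError(f"{path}: not a tile file (bad magic)")
    version, meta_len = struct.unpack_from("<HI", raw, 4)
    if version != _VERSION:
        raise FormatError(f"{path}: unsupported tile-file version {version}")
    digest = raw[10:42]
    payload = raw[42:]
    if hashlib.sha256(payload).digest() != digest:
        raise IntegrityError(f"{path}: payload digest mismatch (truncated/corrupt)")
    meta = json.loads(payload[:meta_len].decode("utf-8"))
    off = meta_len
    n = meta["n_neurons"]

    def take(count, dtype):
        nonlocal off
        arr = np.frombuffer(payload, dtype=dtype, count=count, offset=off)
        off += arr.nbytes
        return arr.copy()

    type_index = take(n, "<u2")
    x = take(n, "<f8"); y = take(n, "<f8"); z = take(n, "<f8")
    bias = take(n, "<f8")
    pre_gids = take(meta["n_pre"], "<i8")
    counts = take(meta["n_pre"], "<i8")
    rec_bytes = meta["n_records"] * RECORD_BYTES
    if off + rec_bytes != len(payload):
        raise IntegrityError(f"{path}: record block size mismatch")
    store = _store_from_payload(pre_gids, counts, payload[off:off + rec_bytes])
    pop = TilePopulation(
        tile_id=meta["tile_id"], x0=meta["x0"], y0=meta["y0"],
        tile_len=meta["tile_len"], gid_start=meta["gid_start"],
        type_index=type_index, x=x, y=y, z=z, bias=bias,
    )
    return store, pop, meta["config_digest"]
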