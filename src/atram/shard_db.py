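"""Sharded paired-end read database.

The library is split into approximately equal shards by hashing the fragment
(pair) id, so each shard holds a random sample of the run. End-1 reads are the
searchable side of each shard; mates are reached only through the shard's mate
store. Searching a fraction of the shards therefore downsamples effective
coverage without bias.

On disk a database is one directory: a ``manifest.txt`` of ``key=value`` lines
plus one TSV per shard (``pair_id<TAB>read1<TAB>read2``). Rebuilding from the
same pairs and salt reproduces the content byte-for-byte.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .seq_io import ReadPair, SequenceRecord

__all__ = [
    "Shard",
    "ShardedDatabase",
    "shard_of",
    "build_database",
    "load_database",
    "fetch_mates",
    "select_shard_subset",
]

MANIFEST_NAME = "manifest.txt"
FORMAT_VERSION = "1"
DEFAULT_SALT = "tram"
DEFAULT_INDEX_KMER = 16
SHARD_TARGET_BYTES = 250 * 1024 * 1024  # reads per shard sized for parallel search


def shard_of(pair_id: str, n_shards: int, salt: str) -> int:
    """Deterministic shard index for a fragment id.

    Uses a salted MD5 so the assignment is stable across runs and platforms
    (language-default string hashing is randomized per process).
    """
    if n_shards < 1:
        raise ValueError("n_shards must be >= 1")
    digest = hashlib.md5((salt + "\x00" + pair_id).encode("utf-8")).digest()
    return int.from_bytes(digest[:8], "big") % n_shards


class Shard:
    """One partition: searchable end-1 reads plus a mate store."""

    def __init__(self, index: int):
        self.index = index
        self.mate_store: dict[str, ReadPair] = {}
        self._order: list[str] = []
        self._kmer_cache: dict[int, dict[str, list[int]]] = {}
        self._protein_cache: dict[int, dict[str, list[int]]] = {}

    def add(self, pair: ReadPair) -> None:
        if pair.pair_id in self.mate_store:
            raise ValueError(f"duplicate pair_id {pair.pair_id!r}")
        self.mate_store[pair.pair_id] = pair
        self._order.append(pair.pair_id)
        self._kmer_cache.clear()
        self._protein_cache.clear()

    def __len__(self) -> int:
        return len(self._order)

    @property
    def pair_ids(self) -> list[str]:
        return self._order

    def reads1(self) -> list[SequenceRecord]:
        """The indexed (end-1) reads, in insertion order."""
        return [self.mate_store[pid].read1 for pid in self._order]

    def search_index(self, k: int) -> dict[str, list[int]]:
        """Canonical k-mer -> postings (positions in :meth:`reads1` order).

        Built lazily at the k a search requests and cached; canonical k-mers
        make both orientations of every indexed read searchable without
        storing reads twice.
        """
        from .search import reverse_complement

        cached = self._kmer_cache.get(k)
        if cached is not None:
            return cached
        index: dict[str, list[int]] = {}
        for ri, pid in enumerate(self._order):
            seq = self.mate_store[pid].read1.sequence
            rc = reverse_complement(seq)
            for off in range(len(seq) - k + 1):
                km = seq[off : off + k]
                kc = rc[len(seq) - k - off : len(seq) - off]
                if kc < km:
                    km = kc
                postings = index.setdefault(km, [])
                if not postings or postings[-1] != ri:
                    postings.append(ri)
        self._kmer_cache[k] = index
        return index

    def protein_index(self, k: int) -> dict[str, list[int]]:
        """Amino-acid k-mer -> postings over all 6 translated frames of end-1 reads."""
        from .search import translate_six_frames

        cached = self._protein_cache.get(k)
        if cached is not None:
            return cached
        index: dict[str, list[int]] = {}
        for ri, pid in enumerate(self._order):
            seen: set[str] = set()
            for frame in translate_six_frames(self.mate_store[pid].read1.sequence):
                for off in range(len(frame) - k + 1):
                    km = frame[off : off + k]
                    if km not in seen:
                        seen.add(km)
                        index.setdefault(km, []).append(ri)
        self._protein_cache[k] = index
        return index


@dataclass
class ShardedDatabase:
    n_shards: int
    shards: list[Shard]
    total_pairs: int
    source_fingerprint: str
    salt: str = DEFAULT_SALT
    index_kmer: int = DEFAULT_INDEX_KMER
    path: Path | None = None

    def shard(self, index: int) -> Shard:
        if not 0 <= index < self.n_shards:
            raise IndexError(f"shard index {index} out of range [0, {self.n_shards})")
        return self.shards[index]


def _fingerprint(pairs: Sequence[ReadPair]) -> str:
    h = hashlib.sha1()
    for p in pairs:
        h.update(p.pair_id.encode())
        h.update(b"\x00")
        h.update(p.read1.sequence.encode())
        h.update(b"\x00")
        h.update(p.read2.sequence.encode())
        h.update(b"\n")
    return h.hexdigest()


def default_shard_count(pairs: Sequence[ReadPair]) -> int:
    total = sum(len(p.read1) + len(p.read2) for p in pairs)
    return max(1, math.ceil(total / SHARD_TARGET_BYTES))


def build_database(
    pairs: Sequence[ReadPair],
    n_shards: int | None = None,
    index_kmer: int = DEFAULT_INDEX_KMER,
    salt: str = DEFAULT_SALT,
    out_dir: str | Path | None = None,
) -> ShardedDatabase:
    """Hash pairs into shards and (optionally) persist the database.

    Both mates of a pair always land in the same shard because the hash is
    keyed on the pair id, never a read id.
    """
    if not pairs:
        raise ValueError("cannot build a database from zero pairs")
    if index_kmer < 8:
        raise ValueError("index_kmer must be >= 8")
    if n_shards is None:
        n_shards = default_shard_count(pairs)
    if n_shards < 1:
        raise ValueError("n_shards must be >= 1")
    shards = [Shard(i) for i in range(n_shards)]
    seen: set[str] = set()
    for p in pairs:
        if p.pair_id in seen:
            raise ValueError(f"duplicate pair_id {p.pair_id!r} in input")
        seen.add(p.pair_id)
        shards[shard_of(p.pair_id, n_shards, salt)].add(p)
    db = ShardedDatabase(
        n_shards=n_shards,
        shards=shards,
        total_pairs=len(pairs),
        source_fingerprint=_fingerprint(pairs),
        salt=salt,
        index_kmer=index_kmer,
    )
    if out_dir is not None:
        save_database(db, out_dir)
    return db


def save_database(db: ShardedDatabase, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / MANIFEST_NAME, "wt") as fh:
        fh.write(f"format_version={FORMAT_VERSION}\n")
        fh.write(f"n_shards={db.n_shards}\n")
        fh.write(f"total_pairs={db.total_pairs}\n")
        fh.write(f"salt={db.salt}\n")
        fh.write(f"index_kmer={db.index_kmer}\n")
        fh.write(f"source_fingerprint={db.source_fingerprint}\n")
    for shard in db.shards:
        with open(out / f"shard_{shard.index:04d}.tsv", "wt") as fh:
            for pid in shard.pair_ids:
                pair = shard.mate_store[pid]
                fh.write(f"{pid}\t{pair.read1.sequence}\t{pair.read2.sequence}\n")
    db.path = out
    return out


def load_database(path: str | Path) -> ShardedDatabase:
    path = Path(path)
    manifest: dict[str, str] = {}
    with open(path / MANIFEST_NAME) as fh:
        for line in fh:
            line = line.strip()
            if line and "=" in line:
                key, _, value = line.partition("=")
                manifest[key] = value
    n_shards = int(manifest["n_shards"])
    shards = []
    total = 0
    for i in range(n_shards):
        shard = Shard(i)
        with open(path / f"shard_{i:04d}.tsv") as fh:
            for line in fh:
                pid, s1, s2 = line.rstrip("\n").split("\t")
                shard.add(
                    ReadPair(
                        pair_id=pid,
                        read1=SequenceRecord(id=pid + "/1", sequence=s1),
                        read2=SequenceRecord(id=pid + "/2", sequence=s2),
                    )
                )
        total += len(shard)
        shards.append(shard)
    db = ShardedDatabase(
        n_shards=n_shards,
        shards=shards,
        total_pairs=total,
        source_fingerprint=manifest.get("source_fingerprint", ""),
        salt=manifest.get("salt", DEFAULT_SALT),
        index_kmer=int(manifest.get("index_kmer", DEFAULT_INDEX_KMER)),
        path=path,
    )
    if total != int(manifest["total_pairs"]):
        raise ValueError(
            f"{path}: manifest says {manifest['total_pairs']} pairs, found {total}"
        )
    return db


def fetch_mates(
    db: ShardedDatabase, shard_index: int, pair_ids: Iterable[str]
) -> list[ReadPair]:
    """Full pairs for every requested id present in the shard.

    Ids living in other shards are silently omitted; the caller queries each
    shard for its own hits.
    """
    shard = db.shard(shard_index)
    out = []
    for pid in sorted(set(pair_ids)):
        pair = shard.mate_store.get(pid)
        if pair is not None:
            out.append(pair)
    return out


def select_shard_subset(db: ShardedDatabase, fraction: float) -> list[int]:
    """First ceil(fraction * n_shards) shard indices.

    Any prefix of shards is a valid downsample because every shard holds a
    random sample of the library.
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    return list(range(math.ceil(fraction * db.n_shards)))
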