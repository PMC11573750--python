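"""Three-party session management.

Two proxies (P0, P1) hold the additive shares and do the work; a helper
(P2) deals correlated randomness and computes on masked values.  The
proxies share a common random tape (same seed, lock-step draws); the
helper never sees it.  Every party additionally owns an independent
seeded generator, so a whole run is reproducible from the four seeds in
the config.

Two interchangeable transports are provided: an in-process simulator
(three threads + queues, used by the tests) and TCP sockets (deployment
realism).  Both frame messages as a 4-byte little-endian length prefix
followed by the payload, and both feed the same per-channel transcript
accounting, so a fixed-seed run produces byte-identical message streams
on either transport.
"""

from __future__ import annotations

import json
import queue
import socket
import struct
import threading
import time
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
import yaml

from .ring import RingSpec

__all__ = [
    "Transcript",
    "Party",
    "Session",
    "SessionConfig",
    "load_config",
    "count_invocations",
    "PROTOCOL_NAMES",
]

ROLES = ("p0", "p1", "helper")

#: protocols whose top-level vectorized invocations are counted
PROTOCOL_NAMES = ("ADD", "MUL", "MP", "TRUNC", "PC", "MOC", "MSB", "CMP", "MUX", "EXP")

_LEN = struct.Struct("<I")


class Transcript:
    """Per-protocol invocation counters plus per-channel message accounting.

    ``record`` additionally keeps the ordered payload log of every
    directed channel, which lets tests assert byte-identical runs across
    transports (global interleaving is scheduler-dependent, per-channel
    order is not).
    """

    def __init__(self, record: bool = False):
        self.record = record
        self.invocations: dict[str, int] = defaultdict(int)
        self.messages: dict[tuple[str, str], int] = defaultdict(int)
        self.bytes: dict[tuple[str, str], int] = defaultdict(int)
        self.log: dict[tuple[str, str], list[bytes]] = defaultdict(list)

    def note_send(self, sender: str, receiver: str, payload: bytes) -> None:
        key = (sender, receiver)
        self.messages[key] += 1
        self.bytes[key] += len(payload)
        if self.record:
            self.log[key].append(payload)

    def count(self, name: str) -> None:
        if name not in PROTOCOL_NAMES:
            raise KeyError(f"unknown protocol name {name!r}")
        self.invocations[name] += 1

    @property
    def total_messages(self) -> int:
        return sum(self.messages.values())

    @property
    def total_bytes(self) -> int:
        return sum(self.bytes.values())

    def merge(self, other: "Transcript") -> None:
        for k, v in other.invocations.items():
            self.invocations[k] += v
        for k, v in other.messages.items():
            self.messages[k] += v
        for k, v in other.bytes.items():
            self.bytes[k] += v
        if self.record:
            for k, v in other.log.items():
                self.log[k].extend(v)


def count_invocations(transcript: Transcript, protocol: str) -> int:
    """Number of top-level vectorized invocations of a named protocol.

    A batched call over a whole vector counts as one invocation.
    """
    if protocol not in PROTOCOL_NAMES:
        raise KeyError(f"unknown protocol name {protocol!r}")
    return transcript.invocations.get(protocol, 0)


# --------------------------------------------------------------------------
# transports


class InProcessTransport:
    """Queue-based message fabric shared by three party threads."""

    def __init__(self):
        self._queues = {
            (a, b): queue.Queue() for a in ROLES for b in ROLES if a != b
        }

    def send(self, sender: str, receiver: str, payload: bytes) -> None:
        self._queues[(sender, receiver)].put(payload)

    def recv(self, sender: str, receiver: str, timeout: float = 120.0) -> bytes:
        return self._queues[(sender, receiver)].get(timeout=timeout)

    def close(self) -> None:
        pass


class _SocketChannel:
    """One duplex peer connection with a writer thread (deadlock-free)."""

    def __init__(self, sock: socket.socket):
        self.sock = sock
        self._outbox: queue.Queue = queue.Queue()
        self._writer = threading.Thread(target=self._write_loop, daemon=True)
        self._writer.start()

    def _write_loop(self) -> None:
        while True:
            payload = self._outbox.get()
            if payload is None:
                break
            try:
                self.sock.sendall(_LEN.pack(len(payload)) + payload)
            except OSError:
                break

    def send(self, payload: bytes) -> None:
        self._outbox.put(payload)

    def recv(self) -> bytes:
        header = self._read_exact(_LEN.size)
        (length,) = _LEN.unpack(header)
        return self._read_exact(length)

    def _read_exact(self, nbytes: int) -> bytes:
        chunks = []
        remaining = nbytes
        while remaining:
            chunk = self.sock.recv(min(remaining, 1 << 20))
            if not chunk:
                raise ConnectionError("peer closed connection")
            chunks.append(chunk)
            remaining -= len(chunk)
        return b"".join(chunks)

    def close(self) -> None:
        self._outbox.put(None)
        self._writer.join(timeout=5)
        try:
            self.sock.close()
        except OSError:
            pass


class SocketTransport:
    """TCP transport for one party; connects pairwise to both peers.

    Connection layout: every role listens on its configured endpoint for
    roles that come later in ``ROLES`` order and dials roles that come
    earlier, retrying until the peer is up.
    """

    def __init__(self, role: str, endpoints: dict[str, tuple[str, int]],
                 connect_timeout: float = 30.0):
        self.role = role
        self.channels: dict[str, _SocketChannel] = {}
        my_index = ROLES.index(role)
        later = [r for r in ROLES if ROLES.index(r) > my_index]
        earlier = [r for r in ROLES if ROLES.index(r) < my_index]

        listener = None
        if later:
            host, port = endpoints[role]
            listener = socket.socket(socket.AF_INET, socket.SOCK_STREAM)
            listener.setsockopt(socket.SOL_SOCKET, socket.SO_REUSEADDR, 1)
            listener.bind((host, port))
            listener.listen(len(later))

        # dial earlier roles
        for peer in earlier:
            host, port = endpoints[peer]
            deadline = time.monotonic() + connect_timeout
            while True:
                try:
                    sock = socket.create_connection((host, port), timeout=5)
                    break
                except OSError:
                    if time.monotonic() > deadline:
                        raise ConnectionError(f"{role}: cannot reach {peer}")
                    time.sleep(0.05)
            sock.setsockopt(socket.IPPROTO_TCP, socket.TCP_NODELAY, 1)
            sock.sendall(role.encode().ljust(8))
            self.channels[peer] = _SocketChannel(sock)

        # accept later roles
        for _ in later:
            assert listener is not None
            sock, _addr = listener.accept()
            sock.setsockopt(socket.IPPROTO_TCP, socket.TCP_NODELAY, 1)
            peer = sock.recv(8).strip().decode()
            self.channels[peer] = _SocketChannel(sock)
        if listener is not None:
            listener.close()

    def send(self, sender: str, receiver: str, payload: bytes) -> None:
        assert sender == self.role
        self.channels[receiver].send(payload)

    def recv(self, sender: str, receiver: str, timeout: float = 120.0) -> bytes:
        assert receiver == self.role
        return self.channels[sender].recv()

    def close(self) -> None:
        for ch in self.channels.values():
            ch.close()


# --------------------------------------------------------------------------
# parties and sessions


class Party:
    """One computing party's view of a session.

    Proxies (pid 0/1) carry the common tape; the helper refuses to hand
    one out.  All sends are routed through the transcript.
    """

    def __init__(self, role: str, spec: RingSpec, transport, *,
                 common_seed: int | None, own_seed: int, record: bool = False):
        if role not in ROLES:
            raise ValueError(f"unknown role {role!r}")
        self.role = role
        self.spec = spec
        self.transport = transport
        self.rng = np.random.Generator(np.random.Philox(own_seed))
        self._tape = None
        if role != "helper":
            if common_seed is None:
                raise ValueError("proxies need the common seed")
            self._tape = np.random.Generator(np.random.Philox(common_seed))
        self.transcript = Transcript(record=record)

    @property
    def pid(self) -> int:
        if self.role == "helper":
            raise ValueError("helper has no proxy index")
        return 0 if self.role == "p0" else 1

    @property
    def is_helper(self) -> bool:
        return self.role == "helper"

    @property
    def tape(self) -> np.random.Generator:
        """Common random generator shared by the proxies only."""
        if self._tape is None:
            raise PermissionError("helper may not access the common tape")
        return self._tape

    @property
    def other(self) -> str:
        return "p1" if self.role == "p0" else "p0"

    # -- messaging --------------------------------------------------------

    def send(self, receiver: str, payload: bytes) -> None:
        self.transcript.note_send(self.role, receiver, payload)
        self.transport.send(self.role, receiver, payload)

    def recv(self, sender: str) -> bytes:
        return self.transport.recv(sender, self.role)

    def exchange(self, payload: bytes) -> bytes:
        """Symmetric proxy-to-proxy swap: send ours, return theirs."""
        if self.is_helper:
            raise PermissionError("exchange is a proxy operation")
        self.send(self.other, payload)
        return self.recv(self.other)

    def send_array(self, receiver: str, arr: np.ndarray) -> None:
        self.send(receiver, np.ascontiguousarray(arr).tobytes())

    def recv_array(self, sender: str, dtype, shape) -> np.ndarray:
        payload = self.recv(sender)
        return np.frombuffer(payload, dtype=dtype).reshape(shape).copy()

    def exchange_array(self, arr: np.ndarray) -> np.ndarray:
        out = self.exchange(np.ascontiguousarray(arr).tobytes())
        return np.frombuffer(out, dtype=arr.dtype).reshape(arr.shape).copy()

    def send_header(self, header: dict) -> None:
        self.send("helper", json.dumps(header, sort_keys=True).encode())

    def count(self, name: str) -> None:
        self.transcript.count(name)


@dataclass
class SessionConfig:
    n: int = 64
    f: int = 20
    exp_base: float = float(np.e)
    transport: str = "inprocess"
    endpoints: dict = field(default_factory=dict)
    common_seed: int = 0
    p0_seed: int = 1
    p1_seed: int = 2
    helper_seed: int = 3
    record: bool = False

    @property
    def spec(self) -> RingSpec:
        return RingSpec(self.n, self.f)


def load_config(path) -> SessionConfig:
    """Read a YAML run configuration (ring.n, ring.f, exp.base, transport,
    per-role endpoints and seeds)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    ring = raw.get("ring", {})
    seeds = raw.get("seeds", {})
    endpoints = {
        role: (str(spec["host"]), int(spec["port"]))
        for role, spec in raw.get("endpoints", {}).items()
    }
    return SessionConfig(
        n=int(ring.get("n", 64)),
        f=int(ring.get("f", 20)),
        exp_base=float(raw.get("exp", {}).get("base", np.e)),
        transport=raw.get("transport", {}).get("mode", "inprocess"),
        endpoints=endpoints,
        common_seed=int(seeds.get("common", 0)),
        p0_seed=int(seeds.get("p0", 1)),
        p1_seed=int(seeds.get("p1", 2)),
        helper_seed=int(seeds.get("helper", 3)),
    )


class Session:
    """Drives one three-party computation.

    ``run(circuit)`` executes ``circuit(party)`` on both proxies while
    the helper serves correlated-randomness requests, and returns the
    two proxies' return values.  The merged transcript is kept on
    ``self.transcript`` afterwards.
    """

    def __init__(self, config: SessionConfig | None = None, **kwargs):
        self.config = config or SessionConfig(**kwargs)
        self.transcript: Transcript | None = None
        self.party_transcripts: dict[str, Transcript] = {}

    def _make_parties(self):
        cfg = self.config
        spec = cfg.spec
        if cfg.transport == "inprocess":
            fabric = InProcessTransport()
            transports = {role: fabric for role in ROLES}
        elif cfg.transport == "socket":
            transports = {}
            holder = {}
            errs = {}

            def _build(role):
                try:
                    holder[role] = SocketTransport(role, cfg.endpoints)
                except Exception as exc:  # pragma: no cover - connection errors
                    errs[role] = exc

            threads = [threading.Thread(target=_build, args=(r,)) for r in ROLES]
            for t in threads:
                t.start()
            for t in threads:
                t.join()
            if errs:
                raise ConnectionError(str(errs))
            transports = holder
        else:
            raise ValueError(f"unknown transport {self.config.transport!r}")

        seeds = {"p0": cfg.p0_seed, "p1": cfg.p1_seed, "helper": cfg.helper_seed}
        parties = {
            role: Party(
                role, spec, transports[role],
                common_seed=None if role == "helper" else cfg.common_seed,
                own_seed=seeds[role], record=cfg.record,
            )
            for role in ROLES
        }
        return parties, transports

    def run(self, circuit, helper_loop=None):
        from . import protocols  # lazy: protocols imports runtime types

        if helper_loop is None:
            helper_loop = protocols.serve_helper

        parties, transports = self._make_parties()
        results: dict[str, object] = {}
        errors: dict[str, BaseException] = {}

        def proxy_main(role):
            try:
                results[role] = circuit(parties[role])
                if role == "p0":
                    protocols.close_helper(parties[role])
            except BaseException as exc:  # noqa: BLE001 - reraised below
                errors[role] = exc

        def helper_main():
            try:
                helper_loop(parties["helper"])
            except BaseException as exc:  # noqa: BLE001
                errors["helper"] = exc

        threads = [
            threading.Thread(target=proxy_main, args=("p0",), daemon=True),
            threading.Thread(target=proxy_main, args=("p1",), daemon=True),
            threading.Thread(target=helper_main, daemon=True),
        ]
        for t in threads:
            t.start()
        # poll so that one party's failure surfaces immediately instead of
        # waiting out the peers' receive timeouts
        while any(t.is_alive() for t in threads):
            if errors:
                break
            for t in threads:
                t.join(timeout=0.02)
        if errors:
            role, exc = next(iter(errors.items()))
            raise RuntimeError(f"party {role} failed") from exc

        if self.config.transport == "socket":
            for tr in transports.values():
                tr.close()

        self.party_transcripts = {r: parties[r].transcript for r in ROLES}
        merged = Transcript(record=self.config.record)
        for r in ROLES:
            merged.merge(parties[r].transcript)
        # invocation counters are kept on P0 only, so merging is safe
        self.transcript = merged
        return results["p0"], results["p1"]
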