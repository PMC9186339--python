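"""Protocol-specific fragment filtering and pooling for hybrid phasing.

Hi-C pairs with apparent insert spans beyond ``hic_max_insert`` (default
40 Mbp) are removed: such contacts are enriched for trans interactions
between the two homologs and inject misleading linkage.  Long-read
observations below ``longread_min_baseq`` (default Q20) are masked, the
standard guard for high per-base error rates.  Fragments left with fewer
than ``min_informative_obs`` observations carry no linkage and are
dropped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from equiphase.iohap import Fragment, Protocol


@dataclass
class FragmentFilterConfig:
    hic_max_insert: int = 40_000_000  # bp; strict ">" removal
    longread_min_baseq: int = 20  # Phred; observations below are masked
    min_informative_obs: int = 2

    def __post_init__(self) -> None:
        if self.hic_max_insert <= 0 or self.longread_min_baseq <= 0 or self.min_informative_obs <= 0:
            raise ValueError("all fragment-filter thresholds must be positive")


def filter_fragments(frags: Iterable[Fragment], cfg: FragmentFilterConfig | None = None) -> list[Fragment]:
    """Apply the per-protocol filters; idempotent.

    * HIC fragments with ``insert_span > hic_max_insert`` are removed.
    * LONGREAD observations with quality < ``longread_min_baseq`` are
      dropped; the fragment survives if enough observations remain.
    * Any fragment with fewer than ``min_informative_obs`` observations
      is removed.
    """
    cfg = cfg or FragmentFilterConfig()
    out: list[Fragment] = []
    for f in frags:
        if f.protocol is Protocol.HIC and f.insert_span > cfg.hic_max_insert:
            continue
        if f.protocol is Protocol.LONGREAD:
            obs = [o for o in f.observations if o[2] >= cfg.longread_min_baseq]
            if len(obs) != len(f.observations):
                if len(obs) < cfg.min_informative_obs:
                    continue
                f = Fragment(f.id, f.protocol, obs, f.insert_span)
        if len(f.observations) < cfg.min_informative_obs:
            continue
        out.append(f)
    return out


_PROTOCOL_ORDER = {Protocol.NGS: 0, Protocol.LONGREAD: 1, Protocol.HIC: 2, Protocol.LINKED: 3}


def pool_fragments(
    sets: Sequence[tuple[Protocol, Sequence[Fragment]]],
    cfg: FragmentFilterConfig | None = None,
) -> list[Fragment]:
    """Filter each protocol set and concatenate into one hybrid pool.

    Output order is stable: NGS, LONGREAD, HIC, LINKED, then input order
    within a protocol.  All sets must be indexed against the same
    het-site ordinals; fragment ids must be unique across sets.
    """
    cfg = cfg or FragmentFilterConfig()
    buckets: dict[Protocol, list[Fragment]] = {p: [] for p in _PROTOCOL_ORDER}
    for protocol, frags in sets:
        for f in frags:
            if f.protocol is not protocol:
                raise ValueError(f"fragment {f.id} tagged {f.protocol.value} in a {protocol.value} set")
        buckets[protocol].extend(filter_fragments(frags, cfg))
    pooled = [f for p in sorted(buckets, key=_PROTOCOL_ORDER.get) for f in buckets[p]]
    ids = [f.id for f in pooled]
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dup = next(i for i in ids if i in seen or seen.add(i))
        raise ValueError(f"duplicate fragment id across sets: {dup!r}")
    return pooled
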