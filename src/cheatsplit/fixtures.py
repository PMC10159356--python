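"""Synthetic fixture generators.

These produce small, fully synthetic CSV inputs for testing and for worked
examples: an illustrative species-estimates table (the shape of a real
parameter-estimate compilation, not measured data), a genus-level table
with a built-in positive DI/multipartitism association, and example
simulation config files.  All outputs are deterministic given the seed.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["FIXTURE_KINDS", "generate_fixtures", "species_frame", "genus_frame"]

FIXTURE_KINDS = ("species_estimates", "genus_table", "sim_config_examples")


def species_frame(seed: int = 0) -> pd.DataFrame:
    """Illustrative per-species estimates (synthetic).

    Two ends of the observed spectrum are always present: a large-deletion
    (defective-interfering) cheat species with c/d ~ 0 and a high
    particle:PFU ratio, and a point-mutation cheat species with a large c/d
    that should require a group benefit at every coinfection level.
    """
    rng = np.random.default_rng(seed)
    rows = [
        # species, cheat_class, c_over_d, particle_pfu, noninfectious_prob
        ("synthetic DI virus A", "large_deletion", 0.0, round(float(rng.uniform(20, 200)), 1), None),
        ("synthetic DI virus B", "large_deletion", round(float(rng.uniform(0.0, 0.05)), 3), round(float(rng.uniform(5, 50)), 1), None),
        ("synthetic DI virus C", "large_deletion", round(float(rng.uniform(0.0, 0.1)), 3), None, round(float(rng.uniform(0.6, 0.95)), 3)),
        ("synthetic DI virus D", "large_deletion", round(float(rng.uniform(0.0, 0.1)), 3), round(float(rng.uniform(2, 20)), 1), None),
        ("synthetic point-mutant virus E", "point_mutation", round(float(rng.uniform(0.55, 0.8)), 3), round(float(rng.uniform(1.0, 3.0)), 2), None),
        ("synthetic point-mutant virus F", "point_mutation", round(float(rng.uniform(0.6, 0.9)), 3), None, round(float(rng.uniform(0.1, 0.4)), 3)),
    ]
    return pd.DataFrame(
        rows,
        columns=["species", "cheat_class", "c_over_d", "particle_pfu", "noninfectious_prob"],
    ).assign(source="synthetic fixture")


def genus_frame(seed: int = 0, n_per_realm: int = 10) -> pd.DataFrame:
    """Synthetic 4-realm genus table with a positive DI/multipartite
    association built in via ordered per-realm fractions (counts are exact,
    so the association survives any seed)."""
    rng = np.random.default_rng(seed)
    # (realm, fraction with DI, fraction multipartite) - jointly increasing
    plan = [
        ("Realm-I", 0.0, 0.0),
        ("Realm-II", 0.2, 0.1),
        ("Realm-III", 0.4, 0.3),
        ("Realm-IV", 0.7, 0.5),
    ]
    rows = []
    for realm, f_di, f_mp in plan:
        n_di = round(f_di * n_per_realm)
        n_mp = round(f_mp * n_per_realm)
        di = np.zeros(n_per_realm, dtype=bool)
        mp = np.zeros(n_per_realm, dtype=bool)
        di[:n_di] = True
        mp[:n_mp] = True
        rng.shuffle(di)
        rng.shuffle(mp)
        for i in range(n_per_realm):
            segs = int(rng.integers(2, 9)) if mp[i] else 1
            rows.append(
                {
                    "genus": f"{realm}-genus-{i + 1:02d}",
                    "realm": realm,
                    "has_di": bool(di[i]),
                    "is_multipartite": bool(mp[i]),
                    "max_segments": segs,
                }
            )
    return pd.DataFrame(rows)


_SIM_CONFIG_EXAMPLES = {
    "sim_fig4_style.cfg": [
        "# 8-gene genome, moderate coinfection (multipartite sweep conditions)",
        "n_genes = 8",
        "moi = 5.0",
        "e = 1.0",
    ],
    "sim_packaging.cfg": [
        "# 2-gene genome with virion copackaging (segmented-virus conditions)",
        "n_genes = 2",
        "moi = 2.0",
        "prop_single = 0.0",
    ],
}


def generate_fixtures(kind: str, seed: int, out_dir) -> list[Path]:
    """Write the requested fixture files into ``out_dir``; returns paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if kind == "species_estimates":
        path = out_dir / "species_estimates.csv"
        species_frame(seed).to_csv(path, index=False)
        return [path]
    if kind == "genus_table":
        path = out_dir / "genus_table.csv"
        genus_frame(seed).to_csv(path, index=False)
        return [path]
    if kind == "sim_config_examples":
        paths = []
        for name, lines in _SIM_CONFIG_EXAMPLES.items():
            path = out_dir / name
            path.write_text("\n".join(lines) + "\n")
            paths.append(path)
        return paths
    raise ValueError(f"unknown fixture kind {kind!r}; choose from {FIXTURE_KINDS}")
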