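"""Named toy models and a deterministic random-model generator.

The toy fixtures are desk-scale stand-ins for genome-scale networks; each
has a documented FBA optimum and exercises one analysis feature:

==================  ==========================================================
TOY_LIN             linear chain upt -> A -> B -> sink; optimum 10
TOY_BRANCH          branch point A feeding two sinks; optimum 10 via exB
TOY_YIELD           2 A -> B stoichiometric yield 1/2; optimum 5
TOY_DEAD            by-product D with no consumer: the whole chain is dead;
                    optimum 0
TOY_REV             reversible isomerase in the chain; optimum 10
PREPHENATE_BRANCH   a branch-point network patterned on aromatic amino-acid
                    biosynthesis: prephenate (turnover 0.72) splits 8% to
                    phenylalanine and 92% to the antibiotic sink (TDA)
==================  ==========================================================

:func:`random_model` generates feasible models of arbitrary size for
property tests: a guaranteed backbone chain from one uptake to the
objective sink plus random extra conversions whose product coefficient
never exceeds the substrate coefficient, so no flux-generating cycle can
arise and every model has a bounded positive optimum.
"""

from __future__ import annotations

import hashlib
import urllib.request

import numpy as np

from .model import MetabolicModel, ModelError, Reaction, Scenario

__all__ = ["FIXTURE_NAMES", "make_fixture", "random_model", "fetch_published_model"]

FIXTURE_NAMES = (
    "TOY_LIN",
    "TOY_BRANCH",
    "TOY_YIELD",
    "TOY_DEAD",
    "TOY_REV",
    "PREPHENATE_BRANCH",
)


def make_fixture(name: str) -> tuple[MetabolicModel, Scenario]:
    """Build a named fixture model + scenario pair."""
    if name == "TOY_LIN":
        model = MetabolicModel(
            reactions=[
                Reaction("upt", {"A": 1.0}),
                Reaction("conv", {"A": -1.0, "B": 1.0}),
                Reaction("bio", {"B": -1.0}),
            ],
            name=name,
        )
        scen = Scenario(upper_bound={"upt": 10.0}, objective=("bio", "max"), name=name)
    elif name == "TOY_BRANCH":
        model = MetabolicModel(
            reactions=[
                Reaction("upt", {"A": 1.0}),
                Reaction("r1", {"A": -1.0, "B": 1.0}),
                Reaction("r2", {"A": -1.0, "C": 1.0}),
                Reaction("exB", {"B": -1.0}),
                Reaction("exC", {"C": -1.0}),
            ],
            name=name,
        )
        scen = Scenario(upper_bound={"upt": 10.0}, objective=("exB", "max"), name=name)
    elif name == "TOY_YIELD":
        model = MetabolicModel(
            reactions=[
                Reaction("upt", {"A": 1.0}),
                Reaction("conv", {"A": -2.0, "B": 1.0}),
                Reaction("bio", {"B": -1.0}),
            ],
            name=name,
        )
        scen = Scenario(upper_bound={"upt": 10.0}, objective=("bio", "max"), name=name)
    elif name == "TOY_DEAD":
        model = MetabolicModel(
            reactions=[
                Reaction("upt", {"A": 1.0}),
                Reaction("conv", {"A": -1.0, "B": 1.0, "D": 1.0}),
                Reaction("bio", {"B": -1.0}),
            ],
            name=name,
        )
        scen = Scenario(upper_bound={"upt": 10.0}, objective=("bio", "max"), name=name)
    elif name == "TOY_REV":
        model = MetabolicModel(
            reactions=[
                Reaction("upt", {"A": 1.0}),
                Reaction("iso", {"A": -1.0, "B": 1.0}, reversible=True),
                Reaction("bio", {"B": -1.0}),
            ],
            name=name,
        )
        scen = Scenario(upper_bound={"upt": 10.0}, objective=("bio", "max"), name=name)
    elif name == "PREPHENATE_BRANCH":
        # Chorismate -> prephenate branch point: prephenate dehydratase (to
        # phenylpyruvate/phenylalanine) competes with the TDA sink.  The
        # uptake bound (0.72) and the phenylalanine demand (0.0576) pin an
        # 8%/92% consumer split at a prephenate turnover of 0.72.
        model = MetabolicModel(
            reactions=[
                Reaction("upt", {"chorismate": 1.0}),
                Reaction("cm", {"chorismate": -1.0, "prephenate": 1.0},
                         annotation="5.4.99.5"),
                Reaction("pdt", {"prephenate": -1.0, "phenylpyruvate": 1.0},
                         annotation="4.2.1.51"),
                Reaction("tda_syn", {"prephenate": -1.0, "tda": 1.0}),
                Reaction("ex_phe", {"phenylpyruvate": -1.0}),
                Reaction("ex_tda", {"tda": -1.0}),
            ],
            name=name,
        )
        scen = Scenario(
            upper_bound={"upt": 0.72},
            lower_bound={"ex_phe": 0.0576},
            objective=("ex_tda", "max"),
            name=name,
        )
    else:
        raise ModelError(f"unknown fixture: {name!r}")
    return model, scen


def random_model(
    n_metabolites: int, n_reactions: int, seed: int
) -> tuple[MetabolicModel, Scenario]:
    """Deterministic feasible random model.

    Requires ``n_reactions >= n_metabolites + 2`` (backbone chain of
    ``n_metabolites + 1`` reactions plus at least one extra).  20% of extra
    conversions are reversible (with equal coefficients); irreversible
    extras may have substrate coefficient 2 and product coefficient <= it,
    so internal loops can never create flux from nothing.
    """
    if n_metabolites < 1:
        raise ModelError("need at least one metabolite")
    if n_reactions < n_metabolites + 2:
        raise ModelError(
            f"need n_reactions >= n_metabolites + 2 ({n_reactions} < {n_metabolites + 2})"
        )
    rng = np.random.default_rng(seed)
    mets = [f"m{i}" for i in range(n_metabolites)]
    model = MetabolicModel(name=f"random_{n_metabolites}x{n_reactions}_s{seed}")
    model.add_reaction(Reaction("upt", {mets[0]: 1.0}))
    for i in range(n_metabolites - 1):
        model.add_reaction(Reaction(f"r{i}", {mets[i]: -1.0, mets[i + 1]: 1.0}))
    model.add_reaction(Reaction("bio", {mets[-1]: -1.0}))
    n_extra = n_reactions - (n_metabolites + 1)
    k = 0
    while k < n_extra:
        a, b = rng.choice(n_metabolites, size=2, replace=False)
        reversible = bool(rng.random() < 0.2)
        c_sub = int(rng.integers(1, 3))
        c_prod = c_sub if reversible else int(rng.integers(1, c_sub + 1))
        model.add_reaction(
            Reaction(f"x{k}", {mets[a]: -float(c_sub), mets[b]: float(c_prod)}, reversible)
        )
        k += 1
    scen = Scenario(upper_bound={"upt": 10.0}, objective=("bio", "max"), name=model.name)
    return model, scen


_PUBLISHED = {
    "iMG481": "https://mmtb.brenda-enzymes.org/models/download/11",
    "iPin571": "https://mmtb.brenda-enzymes.org/models/download/12",
}


def fetch_published_model(which: str, dest: str) -> str:
    """Download one of the two deposited genome-scale models (optional;
    requires network access and is never used by the default test suite).

    The file is sniffed: XML content is converted from SBML, anything else
    is treated as a plain reaction list.  A SHA-256 checksum is written
    alongside.  Returns the path of the plain reaction file.
    """
    if which not in _PUBLISHED:
        raise ModelError(f"unknown model {which!r}; choose from {sorted(_PUBLISHED)}")
    url = _PUBLISHED[which]
    try:
        with urllib.request.urlopen(url, timeout=60) as resp:
            raw = resp.read()
    except Exception as exc:  # noqa: BLE001 - any network failure
        raise RuntimeError(
            f"could not download {which} from {url}: {exc}; "
            "download the file manually and convert it with the CLI"
        ) from exc
    checksum = hashlib.sha256(raw).hexdigest()
    text = raw.decode("utf-8", errors="replace")
    out = f"{dest.rstrip('/')}/{which}.rxn"
    if text.lstrip().startswith("<?xml") or "<sbml" in text[:4000]:
        from .sbmlio import import_sbml_string
        from .rxnfile import write_reaction_file

        model, _ = import_sbml_string(text)
        with open(out, "w") as fh:
            fh.write(write_reaction_file(model))
    else:
        with open(out, "w") as fh:
            fh.write(text)
    with open(out + ".sha256", "w") as fh:
        fh.write(f"{checksum}  {which}\n")
    return out
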