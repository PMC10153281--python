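"""Prompt assembly from named components.

The agent's prompt has four parts, in fixed order: an instruction, API
documentations (Dc.1 for E-utils, Dc.2 for BLAST), API demonstrations
(Dm.1-4, one per database/function pairing), and the test question.  The
first three parts are fixed across tasks; only the question varies.  Which
components are active is a :class:`PromptConfig`: the full setting uses all
seven, the slim setting keeps only the instruction plus the gene-alias
(Dm.1) and alignment (Dm.4) demonstrations, and ablation/probing settings
drop or keep single components.

Component bodies are editable data files (one per component under
``data/prompts/``); the bodies shipped with the package are synthetic
placeholders that honor the structural markup the engine depends on —
bracketed URLs, the ``–>`` call indicator, and an ``Answer:`` line — and can
be replaced wholesale by the user.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path

from entrez_agent.errors import ConfigurationError

#: Chain-of-thought instruction appended after the question in multi-hop
#: mode.  Stored with the typographic apostrophe; an ASCII-apostrophe
#: variant is accepted when configuring from text.
COT_SENTENCE = (
    "Let’s decompose the question to sub-questions and solve them step by step."
)


class ComponentId(str, Enum):
    """Identifiers of the seven prompt components, in rendered order."""

    INSTRUCTION = "instruction"
    DC1 = "dc1"  # E-utils documentation
    DC2 = "dc2"  # BLAST documentation
    DM1 = "dm1"  # gene alias demonstration       (gene,  esearch->efetch)
    DM2 = "dm2"  # gene-SNP demonstration         (snp,   esummary)
    DM3 = "dm3"  # gene-disease demonstration     (omim,  esearch->esummary)
    DM4 = "dm4"  # sequence alignment demonstration (nt,  blastn Put->Get)


#: Rendering order: instruction, then documentations, then demonstrations.
COMPONENT_ORDER: tuple[ComponentId, ...] = tuple(ComponentId)

ABLATABLE: tuple[ComponentId, ...] = tuple(c for c in ComponentId if c is not ComponentId.INSTRUCTION)


@dataclass(frozen=True)
class PromptComponent:
    """One named prompt piece with its database/function metadata."""

    id: ComponentId
    body: str
    database: str = ""
    function: str = ""

    def __post_init__(self) -> None:
        if not self.body.strip():
            raise ConfigurationError(f"component {self.id.value} has an empty body")


@dataclass(frozen=True)
class PromptConfig:
    """An ordered subset of components plus the chain-of-thought switch."""

    included: tuple[ComponentId, ...]
    cot: bool = False
    name: str = ""

    def __post_init__(self) -> None:
        unknown = [c for c in self.included if not isinstance(c, ComponentId)]
        if unknown:
            raise ConfigurationError(f"unknown component ids: {unknown}")
        # canonicalize to rendering order, dropping duplicates
        ordered = tuple(c for c in COMPONENT_ORDER if c in set(self.included))
        object.__setattr__(self, "included", ordered)


FULL = PromptConfig(included=tuple(ComponentId), name="full")
SLIM = PromptConfig(
    included=(ComponentId.INSTRUCTION, ComponentId.DM1, ComponentId.DM4), name="slim"
)


def ablation_configs() -> list[PromptConfig]:
    """Full prompt minus one component, for each of Dc.1-2 and Dm.1-4."""
    return [
        PromptConfig(
            included=tuple(c for c in ComponentId if c is not removed),
            name=f"ablate:{removed.value}",
        )
        for removed in ABLATABLE
    ]


def probe_configs() -> list[PromptConfig]:
    """Instruction plus exactly one documentation or demonstration."""
    return [
        PromptConfig(
            included=(ComponentId.INSTRUCTION, kept), name=f"probe:{kept.value}"
        )
        for kept in ABLATABLE
    ]


@dataclass
class ComponentStore:
    """Loaded component bodies, keyed by id.

    By default the store reads the package's ``data/prompts`` directory: a
    ``manifest.json`` mapping component id to filename plus database and
    function tags, and one UTF-8 text file per component.
    """

    components: dict[ComponentId, PromptComponent] = field(default_factory=dict)

    @classmethod
    def load(cls, directory: str | Path | None = None) -> "ComponentStore":
        if directory is None:
            directory = resources.files("entrez_agent").joinpath("data/prompts")
        else:
            directory = Path(directory)
        manifest = json.loads(directory.joinpath("manifest.json").read_text("utf-8"))
        components: dict[ComponentId, PromptComponent] = {}
        for cid_text, meta in manifest["components"].items():
            cid = ComponentId(cid_text)
            body = directory.joinpath(meta["file"]).read_text("utf-8")
            components[cid] = PromptComponent(
                id=cid,
                body=body,
                database=meta.get("database", ""),
                function=meta.get("function", ""),
            )
        return cls(components=components)

    def body(self, cid: ComponentId) -> str:
        try:
            return self.components[cid].body
        except KeyError:
            raise ConfigurationError(
                f"no body loaded for component {cid.value}"
            ) from None


def assemble_prompt(
    config: PromptConfig, question: str, store: ComponentStore | None = None
) -> str:
    """Render the prompt: components in fixed order, question last.

    Components are separated by one blank line; the question block is
    ``Question: <text>`` followed by the chain-of-thought sentence when
    ``config.cot`` is set.  Identical inputs yield byte-identical output.
    """
    if not question.strip():
        raise ConfigurationError("question must be non-empty")
    if store is None:
        store = ComponentStore.load()
    blocks = [store.body(cid).strip("\n") for cid in config.included]
    question_block = f"Question: {question.strip()}"
    if config.cot:
        question_block += "\n" + COT_SENTENCE
    blocks.append(question_block)
    return "\n\n".join(blocks) + "\n"


def config_from_name(name: str, cot: bool = False) -> PromptConfig:
    """Resolve ``full``, ``slim``, ``ablate:<id>``, or ``probe:<id>``."""
    if name == "full":
        base = FULL
    elif name == "slim":
        base = SLIM
    elif name.startswith("ablate:"):
        removed = ComponentId(name.split(":", 1)[1])
        base = PromptConfig(
            included=tuple(c for c in ComponentId if c is not removed), name=name
        )
    elif name.startswith("probe:"):
        kept = ComponentId(name.split(":", 1)[1])
        base = PromptConfig(included=(ComponentId.INSTRUCTION, kept), name=name)
    else:
        raise ConfigurationError(f"unknown prompt config name: {name!r}")
    if cot:
        return PromptConfig(included=base.included, cot=True, name=base.name)
    return base
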