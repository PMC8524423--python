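"""Partitioning generated artifacts into implementation guides and writing
the IG source trees.

Profiles are owned by exactly one guide: profiles tagged ``core`` — or built
from entries of more than one program — live in the shared Core guide that
FP and STI both depend on; the rest go to their program's guide.  A value
set follows the lowest common guide of the profiles that reference it (a set
used by both programs is promoted to Core alongside them), and a generated
CodeSystem follows its value set.

The output layout follows the de-facto IG-publisher input convention
(``input/resources``, ``input/pagecontent``, an NPM-style ``package.json``)
but no publisher is ever invoked.  Re-running on unchanged input rewrites a
byte-identical tree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .conformance import (CodeSystemDefinition, EmitConfig, ProfileDefinition,
                          ValueSetDefinition, emit_code_system,
                          emit_structure_definition, emit_value_set,
                          to_json_bytes)
from .errors import AssignmentError, EmitError

GUIDE_TITLES = {"core": "Core Implementation Guide",
                "fp": "Family Planning Implementation Guide",
                "sti": "Sexually Transmitted Infections Implementation Guide"}


@dataclass
class IGPackage:
    """One implementation guide: profiles, value sets, manifest."""

    guide_id: str
    title: str
    canonical_base: str
    profiles: list[ProfileDefinition] = field(default_factory=list)
    value_sets: list[ValueSetDefinition] = field(default_factory=list)
    code_systems: list[CodeSystemDefinition] = field(default_factory=list)
    dependencies: list[str] = field(default_factory=list)

    @property
    def package_id(self) -> str:
        return f"dak.{self.guide_id}"

    @property
    def ig_resource_id(self) -> str:
        return f"dak-{self.guide_id}"


def assign_guides(profiles: list[ProfileDefinition],
                  value_sets: list[ValueSetDefinition],
                  canonical_base: str,
                  guide_ids: tuple[str, ...] = ("core", "fp", "sti"),
                  ) -> list[IGPackage]:
    """Partition profiles and value sets into Core and per-program guides.

    Every profile must carry a program tag from ``guide_ids``; profiles whose
    entries span both programs arrive already tagged ``core`` (promotion
    happens at profile build time).  Value sets land in the lowest common
    guide of their referencing profiles; unreferenced ones default to Core.
    """
    packages = {gid: IGPackage(guide_id=gid,
                               title=GUIDE_TITLES.get(gid, gid.upper()),
                               canonical_base=canonical_base,
                               dependencies=[] if gid == "core" else ["core"])
                for gid in guide_ids}

    seen_ids: set[str] = set()
    for prof in sorted(profiles, key=lambda p: p.id):
        if prof.program not in packages:
            raise AssignmentError(prof.id, f"unknown program tag {prof.program!r}")
        if prof.id in seen_ids:
            raise AssignmentError(prof.id, "profile id assigned twice")
        seen_ids.add(prof.id)
        packages[prof.program].profiles.append(prof)

    # lowest common guide of the referencing profiles
    referencing: dict[str, set[str]] = {}
    for prof in profiles:
        for c in prof.constraints:
            if c.binding_url:
                referencing.setdefault(c.binding_url, set()).add(prof.program)
    for vs in sorted(value_sets, key=lambda v: v.id):
        programs = referencing.get(vs.canonical_url, set())
        home = next(iter(programs)) if len(programs) == 1 else "core"
        packages[home].value_sets.append(vs)
        if vs.local_code_system is not None:
            packages[home].code_systems.append(vs.local_code_system)
    return [packages[gid] for gid in guide_ids]


def render_differential_table(profile: ProfileDefinition) -> str:
    """Human-readable Markdown differential for one profile."""
    lines = [f"# {profile.name}",
             "",
             f"Differential on base resource **{profile.resource_type}** "
             f"(`{profile.base}`).",
             "",
             "| Path | Card. | Type | Fixed value | Binding |",
             "|---|---|---|---|---|"]
    for c in profile.constraints:
        card = f"{c.min if c.min is not None else 0}..{c.max or '*'}"
        fixed = (f"{c.fixed_system}|{c.fixed_value}" if c.fixed_system
                 else c.fixed_value)
        binding = (f"{c.binding_url} ({c.binding_strength})"
                   if c.binding_url else "")
        path = f"{profile.resource_type}.{c.path}" if c.path else profile.resource_type
        lines.append(f"| {path} | {card} | {c.type} | {fixed} | {binding} |")
    return "\n".join(lines) + "\n"


def emit_ig_resource(pkg: IGPackage, config: EmitConfig) -> dict:
    """The ImplementationGuide R4 resource enumerating every artifact."""
    resources = []
    for prof in pkg.profiles:
        resources.append({
            "reference": {"reference": f"StructureDefinition/{prof.id}"},
            "name": prof.name,
            "exampleBoolean": False,
        })
    for vs in pkg.value_sets:
        resources.append({
            "reference": {"reference": f"ValueSet/{vs.id}"},
            "name": vs.name,
            "exampleBoolean": False,
        })
    for cs in pkg.code_systems:
        resources.append({
            "reference": {"reference": f"CodeSystem/{cs.id}"},
            "name": cs.name,
            "exampleBoolean": False,
        })
    doc = {
        "resourceType": "ImplementationGuide",
        "id": pkg.ig_resource_id,
        "url": f"{pkg.canonical_base.rstrip('/')}/ImplementationGuide/{pkg.ig_resource_id}",
        "version": config.version,
        "name": "".join(p.capitalize() for p in pkg.title.split()),
        "title": pkg.title,
        "status": "draft",
        "packageId": pkg.package_id,
        "fhirVersion": [config.fhir_version],
        "definition": {"resource": resources},
    }
    if pkg.dependencies:
        doc["dependsOn"] = [
            {"uri": f"{pkg.canonical_base.rstrip('/')}/ImplementationGuide/dak-{dep}",
             "packageId": f"dak.{dep}", "version": config.version}
            for dep in pkg.dependencies]
    return doc


def emit_manifest(pkg: IGPackage, config: EmitConfig) -> dict:
    """NPM-style package manifest."""
    return {
        "name": pkg.package_id,
        "version": config.version,
        "fhirVersions": [config.fhir_version],
        "dependencies": {f"dak.{dep}": config.version for dep in pkg.dependencies},
    }


def _write(path: Path, data: bytes, overwrite: bool) -> Path:
    if path.exists():
        if path.read_bytes() == data:
            return path
        if not overwrite:
            raise EmitError(str(path))
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_bytes(data)
    return path


def emit_ig(pkg: IGPackage, outdir: str | Path,
            config: EmitConfig | None = None,
            overwrite: bool = False) -> list[Path]:
    """Write one guide's complete source tree under ``outdir/<guide_id>``.

    Layout::

        <guide_id>/package.json
        <guide_id>/input/ImplementationGuide-<id>.json
        <guide_id>/input/resources/StructureDefinition-<id>.json ...
        <guide_id>/input/pagecontent/index.md, <profile-id>.md ...

    Returns the list of files written.  A collision with a differing
    existing file raises :class:`EmitError` unless ``overwrite`` is set.
    """
    config = config or EmitConfig(canonical_base=pkg.canonical_base)
    root = Path(outdir) / pkg.guide_id
    written: list[Path] = []

    written.append(_write(root / "package.json",
                          to_json_bytes(emit_manifest(pkg, config)), overwrite))
    written.append(_write(root / "input" / f"ImplementationGuide-{pkg.ig_resource_id}.json",
                          to_json_bytes(emit_ig_resource(pkg, config)), overwrite))
    res = root / "input" / "resources"
    pages = root / "input" / "pagecontent"
    for prof in pkg.profiles:
        written.append(_write(res / f"StructureDefinition-{prof.id}.json",
                              to_json_bytes(emit_structure_definition(prof, config)),
                              overwrite))
        written.append(_write(pages / f"{prof.id}.md",
                              render_differential_table(prof).encode("utf-8"),
                              overwrite))
    for vs in pkg.value_sets:
        written.append(_write(res / f"ValueSet-{vs.id}.json",
                              to_json_bytes(emit_value_set(vs, config)), overwrite))
    for cs in pkg.code_systems:
        written.append(_write(res / f"CodeSystem-{cs.id}.json",
                              to_json_bytes(emit_code_system(cs, config)), overwrite))

    index = [f"# {pkg.title}", "",
             f"{len(pkg.profiles)} profiles, {len(pkg.value_sets)} value sets, "
             f"{len(pkg.code_systems)} code systems.", "", "## Profiles", ""]
    index += [f"- [{p.name}]({p.id}.md)" for p in pkg.profiles]
    written.append(_write(pages / "index.md",
                          ("\n".join(index) + "\n").encode("utf-8"), overwrite))
    return written
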