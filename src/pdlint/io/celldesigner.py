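"""CellDesigner-flavoured SBML reader/writer (defined subset).

Targets SBML Level 2 with the CellDesigner 4.x extension namespace.  Only
the subset needed for PD-map auditing is honoured:

* species with a CellDesigner ``speciesIdentity`` of class PROTEIN or
  COMPLEX, protein references, and per-species modification states
  (``residue``/``state`` pairs, with ``phosphorylated`` for "P" and
  ``empty`` for an unset variable);
* proteins with ``listOfModificationResidues`` declaring the site tokens;
* reactions with reactant/product/modifier lists and a modification type
  (CATALYSIS / PHYSICAL_STIMULATION).

Constructs the package adds on top of plain CellDesigner (generic-pool
membership, complex composition by pool id, exact process kinds and
modulation classes) are carried in a small auxiliary annotation namespace so
round-trips are lossless.  Unsupported constructs are skipped with a logged
warning, never silently dropped.
"""

from __future__ import annotations

import logging
import os
from pathlib import Path
from typing import Optional, Union

from lxml import etree

from pdlint.model import (
    ASSOCIATION,
    CATALYSIS,
    DISSOCIATION,
    GENERIC_PROCESS,
    STATE_TRANSITION,
    STIMULATION,
    UNKNOWN_MODULATION,
    UNSET,
    PHOSPHORYLATED,
    ComplexPool,
    MapModel,
    Process,
    ProteinPool,
    StateVariable,
    normalize_protein_identity,
)

logger = logging.getLogger("pdlint.io.celldesigner")

SBML_NS = "http://www.sbml.org/sbml/level2/version4"
CD_NS = "http://www.sbml.org/2001/ns/celldesigner"
PDL_NS = "urn:pdlint:map:1"

NSMAP = {None: SBML_NS, "celldesigner": CD_NS, "pdl": PDL_NS}


def _sbml(tag: str) -> str:
    return f"{{{SBML_NS}}}{tag}"


def _cd(tag: str) -> str:
    return f"{{{CD_NS}}}{tag}"


def _pdl(tag: str) -> str:
    return f"{{{PDL_NS}}}{tag}"


class CellDesignerParseError(ValueError):
    """The file is not parseable as the supported CellDesigner-SBML subset."""


_KIND_TO_CD = {
    STATE_TRANSITION: "STATE_TRANSITION",
    ASSOCIATION: "HETERODIMER_ASSOCIATION",
    DISSOCIATION: "DISSOCIATION",
    GENERIC_PROCESS: "STATE_TRANSITION",
}
_CD_TO_KIND = {
    "STATE_TRANSITION": STATE_TRANSITION,
    "HETERODIMER_ASSOCIATION": ASSOCIATION,
    "DISSOCIATION": DISSOCIATION,
    "TRANSPORT": STATE_TRANSITION,
}
_MOD_TO_CD = {
    CATALYSIS: "CATALYSIS",
    STIMULATION: "PHYSICAL_STIMULATION",
    UNKNOWN_MODULATION: "MODULATION",
}
_CD_TO_MOD = {
    "CATALYSIS": CATALYSIS,
    "UNKNOWN_CATALYSIS": CATALYSIS,
    "PHYSICAL_STIMULATION": STIMULATION,
    "MODULATION": UNKNOWN_MODULATION,
}


def _state_to_cd(value: str) -> str:
    if value == PHOSPHORYLATED:
        return "phosphorylated"
    if value == UNSET:
        return "empty"
    return value


def _state_from_cd(value: str) -> str:
    if value == "phosphorylated":
        return PHOSPHORYLATED
    if value == "empty":
        return UNSET
    return value


# -- writing -------------------------------------------------------------------


def write_celldesigner(model: MapModel, path: Union[str, os.PathLike]) -> None:
    model.validate()
    root = etree.Element(_sbml("sbml"), nsmap=NSMAP, level="2", version="4")
    mdl = etree.SubElement(root, _sbml("model"))
    mdl.set("id", "m1")
    mdl.set("name", model.map_name)

    ann = etree.SubElement(mdl, _sbml("annotation"))
    ext = etree.SubElement(ann, _cd("extension"))
    etree.SubElement(ext, _cd("modelVersion")).text = "4.0"

    # protein table: one entry per protein key, residues = union over pools
    key_sites: dict[str, list[str]] = {}
    key_labels: dict[str, str] = {}
    for pool in model.protein_pools():
        sites = key_sites.setdefault(pool.protein_key, [])
        for sv in sorted(pool.state, key=lambda s: s.site):
            if sv.site not in sites:
                sites.append(sv.site)
        key_labels.setdefault(pool.protein_key, pool.label)
    protein_ids: dict[str, str] = {}
    residue_ids: dict[tuple[str, str], str] = {}
    lop = etree.SubElement(ext, _cd("listOfProteins"))
    for n, key in enumerate(sorted(key_sites), start=1):
        prid = f"pr{n}"
        protein_ids[key] = prid
        pr = etree.SubElement(lop, _cd("protein"))
        pr.set("id", prid)
        pr.set("name", key_labels[key])
        pr.set("type", "PROTEIN")
        if key_sites[key]:
            lomr = etree.SubElement(pr, _cd("listOfModificationResidues"))
            for i, site in enumerate(sorted(key_sites[key]), start=1):
                res = etree.SubElement(lomr, _cd("modificationResidue"))
                res.set("id", f"{prid}_rs{i}")
                res.set("name", site)
                residue_ids[(key, site)] = f"{prid}_rs{i}"

    loc = etree.SubElement(mdl, _sbml("listOfCompartments"))
    for comp in sorted(model.compartments):
        c = etree.SubElement(loc, _sbml("compartment"))
        c.set("id", comp)
        c.set("name", comp)

    los = etree.SubElement(mdl, _sbml("listOfSpecies"))
    for pool in model.protein_pools():
        sp = etree.SubElement(los, _sbml("species"))
        sp.set("id", pool.pool_id)
        sp.set("name", pool.label)
        sp.set("compartment", pool.compartment)
        sann = etree.SubElement(sp, _sbml("annotation"))
        sext = etree.SubElement(sann, _cd("extension"))
        ident = etree.SubElement(sext, _cd("speciesIdentity"))
        etree.SubElement(ident, _cd("class")).text = "PROTEIN"
        pref = etree.SubElement(ident, _cd("proteinReference"))
        pref.text = protein_ids[pool.protein_key]
        if pool.state:
            st = etree.SubElement(ident, _cd("state"))
            lom = etree.SubElement(st, _cd("listOfModifications"))
            for sv in sorted(pool.state, key=lambda s: s.site):
                m = etree.SubElement(lom, _cd("modification"))
                m.set("residue", residue_ids[(pool.protein_key, sv.site)])
                m.set("state", _state_to_cd(sv.value))
        info = etree.SubElement(sann, _pdl("pool"))
        info.set("proteinKey", pool.protein_key)
        if pool.uniprot_ids:
            info.set("uniprot", " ".join(sorted(pool.uniprot_ids)))
        if pool.is_generic:
            info.set("generic", "true")
            if pool.members:
                info.set("members", " ".join(sorted(pool.members)))
    for cx in model.complex_pools():
        sp = etree.SubElement(los, _sbml("species"))
        sp.set("id", cx.pool_id)
        sp.set("name", cx.pool_id)
        sp.set("compartment", cx.compartment)
        sann = etree.SubElement(sp, _sbml("annotation"))
        sext = etree.SubElement(sann, _cd("extension"))
        ident = etree.SubElement(sext, _cd("speciesIdentity"))
        etree.SubElement(ident, _cd("class")).text = "COMPLEX"
        info = etree.SubElement(sann, _pdl("complex"))
        info.set("components", " ".join(cx.components))

    if model.processes:
        lor = etree.SubElement(mdl, _sbml("listOfReactions"))
        for proc in (model.processes[k] for k in sorted(model.processes)):
            rx = etree.SubElement(lor, _sbml("reaction"))
            rx.set("id", proc.process_id)
            rx.set("reversible", "false")
            rann = etree.SubElement(rx, _sbml("annotation"))
            rext = etree.SubElement(rann, _cd("extension"))
            etree.SubElement(rext, _cd("reactionType")).text = _KIND_TO_CD[proc.kind]
            pinfo = etree.SubElement(rann, _pdl("process"))
            pinfo.set("kind", proc.kind)
            if proc.reactants:
                lr = etree.SubElement(rx, _sbml("listOfReactants"))
                for rid in proc.reactants:
                    etree.SubElement(lr, _sbml("speciesReference")).set("species", rid)
            if proc.products:
                lp = etree.SubElement(rx, _sbml("listOfProducts"))
                for pid in proc.products:
                    etree.SubElement(lp, _sbml("speciesReference")).set("species", pid)
            if proc.modulators:
                lm = etree.SubElement(rx, _sbml("listOfModifiers"))
                for pid, cls in proc.modulators:
                    mref = etree.SubElement(lm, _sbml("modifierSpeciesReference"))
                    mref.set("species", pid)
                    mann = etree.SubElement(mref, _sbml("annotation"))
                    mext = etree.SubElement(mann, _cd("extension"))
                    lmod = etree.SubElement(mext, _cd("listOfModification"))
                    mm = etree.SubElement(lmod, _cd("modification"))
                    mm.set("type", _MOD_TO_CD[cls])
                    mm.set("modifiers", pid)
                    minfo = etree.SubElement(mann, _pdl("modulation"))
                    minfo.set("class", cls)

    tree = etree.ElementTree(root)
    tree.write(
        str(path), xml_declaration=True, encoding="UTF-8", pretty_print=True
    )


# -- reading -------------------------------------------------------------------


def read_celldesigner(
    path: Union[str, os.PathLike], map_name: Optional[str] = None
) -> MapModel:
    """Parse a CellDesigner-SBML file into a validated MapModel.

    ``map_name`` overrides the SBML model name; the file stem is the last
    fallback.  Malformed XML raises :class:`CellDesignerParseError`;
    unsupported constructs are skipped with a logged warning.
    """
    try:
        tree = etree.parse(str(path))
    except (etree.XMLSyntaxError, OSError) as exc:
        raise CellDesignerParseError(f"cannot parse {path}: {exc}") from exc
    root = tree.getroot()
    mdl = root.find(_sbml("model"))
    if mdl is None:
        raise CellDesignerParseError(f"{path}: no SBML <model> element")

    name = map_name or mdl.get("name") or mdl.get("id") or Path(path).stem
    model = MapModel(map_name=name, provenance=str(path))

    for comp in mdl.iterfind(f"{_sbml('listOfCompartments')}/{_sbml('compartment')}"):
        model.compartments.add(comp.get("id") or "default")

    # CellDesigner protein table: protein id -> (name, residue id -> site)
    proteins: dict[str, tuple[str, dict[str, str]]] = {}
    for pr in mdl.iter(_cd("protein")):
        residues = {}
        for res in pr.iter(_cd("modificationResidue")):
            residues[res.get("id")] = res.get("name") or res.get("id")
        proteins[pr.get("id")] = (pr.get("name") or pr.get("id"), residues)

    deferred_complexes = []
    for sp in mdl.iterfind(f"{_sbml('listOfSpecies')}/{_sbml('species')}"):
        sid = sp.get("id")
        ident = sp.find(f".//{_cd('speciesIdentity')}")
        if ident is None:
            logger.warning(
                "%s: species %s has no CellDesigner identity; skipped", path, sid
            )
            continue
        cls_el = ident.find(_cd("class"))
        cls = (cls_el.text or "").strip() if cls_el is not None else ""
        if cls == "PROTEIN":
            label = sp.get("name") or sid
            pref = ident.find(_cd("proteinReference"))
            residues: dict[str, str] = {}
            if pref is not None and pref.text in proteins:
                pname, residues = proteins[pref.text]
                if not sp.get("name"):
                    label = pname
            state = []
            for m in ident.iterfind(f".//{_cd('modification')}"):
                res_ref = m.get("residue") or ""
                site = residues.get(res_ref, res_ref)
                state.append(StateVariable(site, _state_from_cd(m.get("state") or "")))
            info = sp.find(f".//{_pdl('pool')}")
            uniprot = frozenset((info.get("uniprot") or "").split()) if info is not None else frozenset()
            is_generic = info is not None and info.get("generic") == "true"
            members = (
                frozenset((info.get("members") or "").split())
                if info is not None
                else frozenset()
            )
            key = (
                info.get("proteinKey")
                if info is not None and info.get("proteinKey")
                else normalize_protein_identity(label, uniprot)
            )
            model.add_protein(
                ProteinPool(
                    pool_id=sid,
                    label=label,
                    protein_key=key,
                    uniprot_ids=uniprot,
                    is_generic=is_generic,
                    members=members,
                    state=frozenset(state),
                    compartment=sp.get("compartment") or "default",
                )
            )
        elif cls == "COMPLEX":
            info = sp.find(f".//{_pdl('complex')}")
            if info is None or not (info.get("components") or "").split():
                logger.warning(
                    "%s: complex species %s lacks component annotation; skipped",
                    path,
                    sid,
                )
                continue
            deferred_complexes.append(
                (sid, tuple(info.get("components").split()), sp.get("compartment") or "default")
            )
        else:
            logger.warning(
                "%s: species %s of unsupported class %r skipped", path, sid, cls
            )
    for sid, components, compartment in deferred_complexes:
        model.add_complex(
            ComplexPool(pool_id=sid, components=components, compartment=compartment)
        )

    for rx in mdl.iterfind(f"{_sbml('listOfReactions')}/{_sbml('reaction')}"):
        rid = rx.get("id")
        pinfo = rx.find(f".//{_pdl('process')}")
        if pinfo is not None and pinfo.get("kind"):
            kind = pinfo.get("kind")
        else:
            rt = rx.find(f".//{_cd('reactionType')}")
            kind = _CD_TO_KIND.get(
                (rt.text or "").strip() if rt is not None else "", STATE_TRANSITION
            )
        reactants = [
            sr.get("species")
            for sr in rx.iterfind(
                f"{_sbml('listOfReactants')}/{_sbml('speciesReference')}"
            )
        ]
        products = [
            sr.get("species")
            for sr in rx.iterfind(
                f"{_sbml('listOfProducts')}/{_sbml('speciesReference')}"
            )
        ]
        modulators = []
        for mref in rx.iterfind(
            f"{_sbml('listOfModifiers')}/{_sbml('modifierSpeciesReference')}"
        ):
            minfo = mref.find(f".//{_pdl('modulation')}")
            if minfo is not None and minfo.get("class"):
                cls = minfo.get("class")
            else:
                mtype = mref.find(f".//{_cd('modification')}")
                cls = _CD_TO_MOD.get(
                    mtype.get("type") if mtype is not None else "", UNKNOWN_MODULATION
                )
            modulators.append((mref.get("species"), cls))
        known = set(model.pools) | set(model.complexes)
        refs = reactants + products + [pid for pid, _ in modulators]
        missing = [r for r in refs if r not in known]
        if missing:
            logger.warning(
                "%s: reaction %s references skipped species %s; reaction skipped",
                path,
                rid,
                missing,
            )
            continue
        model.add_process(
            Process(
                process_id=rid,
                kind=kind,
                reactants=tuple(reactants),
                products=tuple(products),
                modulators=tuple(modulators),
            )
        )
    return model.validate()
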