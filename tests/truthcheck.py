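"""Shared helper: compare a pipeline report against a generator truth set."""

from __future__ import annotations

from spliceatlas import GeneLocus, TruthSet
from spliceatlas.report import annotate


def verify_locus_against_truth(locus: GeneLocus, truth: TruthSet) -> list:
    """Return a list of discrepancies (empty = full recovery)."""
    rep = annotate(locus)
    probs = []

    fx = {r["transcript_id"]: r for r in rep.first_exons}
    for tid, want in truth.first_exon_calls.items():
        got = fx[tid]
        if (
            got["class"] != want["class"]
            or got["anchor_exon"] != want["anchor"]
            or got["retained_nt"] != want["retained_nt"]
        ):
            probs.append(("first_exon", tid, want, got))

    ev_by_tid: dict[str, list] = {}
    for r in rep.events:
        ev_by_tid.setdefault(r["transcript_id"], []).append(r)
    for tid, wants in truth.events.items():
        gots = ev_by_tid.get(tid, [])
        if len(gots) != len(wants):
            probs.append(("event_count", tid, wants, gots))
            continue
        for w, g in zip(wants, gots):
            if (
                g["kind"] != w["kind"]
                or g["ref_exons"] != w["ref_exons"]
                or g["delta_nt"] != w["delta_nt"]
            ):
                probs.append(("event", tid, w, g))
            if "nagnag" in w and g["nagnag"] != w["nagnag"]:
                probs.append(("nagnag", tid, w, g))

    cons_by: dict[str, list] = {}
    for r in rep.consequences:
        cons_by.setdefault(r["transcript_id"], []).append(r)
    for tid, want in truth.consequences.items():
        gots = cons_by.get(tid, [])
        if not gots:
            probs.append(("no_consequence", tid, want))
            continue
        g = gots[0]
        if g["category"] != want["category"]:
            probs.append(("category", tid, want, g))
            continue
        if want["category"].startswith("inframe"):
            if g["deleted_residues"] != want.get("deleted", 0) or g[
                "inserted_residues"
            ] != want.get("inserted", 0):
                probs.append(("counts", tid, want, g))
            nsub = len(g["substitutions"].split(";")) if g["substitutions"] else 0
            if nsub != want.get("n_subs", 0):
                probs.append(("substitutions", tid, want, g))
        if want["category"] == "frameshift_ptc" and g["nmd_candidate"] != want["nmd_candidate"]:
            probs.append(("nmd", tid, want, g))
        if want["category"] == "n_terminal_truncation":
            t = want["truncation"]
            got_t = (g.get("unique_n"), g.get("missing_n"), g.get("shared_suffix"))
            if got_t != (t["unique_n"], t["missing_n"], t["shared_suffix"]):
                probs.append(("truncation", tid, want, g))

    got_cl = sorted(
        (c["n_members"], c["width"], c["shape"], c["tata"]) for c in rep.tss_clusters
    )
    want_cl = sorted((c["size"], c["width"], c["shape"], c["tata"]) for c in truth.tss_clusters)
    if got_cl != want_cl:
        probs.append(("tss_clusters", want_cl, got_cl))

    got_p = sorted(tuple(sorted((p["a"], p["b"]))) for p in rep.me_pairs)
    want_p = sorted(tuple(sorted(p)) for p in truth.me_pairs)
    if got_p != want_p:
        probs.append(("me_pairs", want_p, got_p))
    return probs
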