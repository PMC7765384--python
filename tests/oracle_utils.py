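"""Independent brute-force oracle and random in-memory variant sets.

The oracle re-states each screening rule as one plain conjunction evaluated
record by record, sharing no code with the cascade module, so the two routes
can disagree if either is wrong.
"""

import numpy as np

import triosift as ts

CONSEQUENCES = [c for c in ts.Consequence]
CLASSES = [c for c in ts.Classification]


def brute_force_candidates(vset, design, cfg):
    """Conjunction-of-rules filter; returns the set of surviving keys."""
    keep = set()
    for rec in vset:
        ann = rec.annotation
        if ann.pop_af is None:
            af_ok = cfg.missing_af_passes
        else:
            af_ok = ann.pop_af < cfg.af_threshold

        shared_ok = True
        for sid in design.affected_ids:
            call = rec.calls[sid]
            if call.alleles is None:
                if cfg.affected_missing_gt_policy == "strict_drop":
                    shared_ok = False
            elif 1 not in call.alleles:
                shared_ok = False

        control_ok = True
        for sid in design.unaffected_ids:
            call = rec.calls[sid]
            if call.alleles is None:
                if cfg.unaffected_missing_gt_policy == "strict_drop":
                    control_ok = False
            elif 1 in call.alleles:
                control_ok = False

        class_ok = not (
            ann.classification is not None and ann.classification in cfg.excluded_classes
        )
        cons_ok = ann.consequence in cfg.allowed_consequences
        snv_ok = rec.is_snv or not cfg.snv_only

        depth_ok = True
        for sid in design.sample_ids:
            dp = rec.calls[sid].depth
            if dp is not None and dp < cfg.min_depth:
                depth_ok = False

        report_ok = ann.consequence in cfg.report_consequences

        if all([af_ok, shared_ok, control_ok, class_ok, cons_ok, snv_ok, depth_ok, report_ok]):
            keep.add(rec.key)
    return keep


def random_vset(seed: int, n: int, sample_ids=("A1", "A2", "U1")) -> ts.VariantSet:
    """A random in-memory variant set stressing every filter dimension."""
    rng = np.random.default_rng(seed)
    records = []
    positions = rng.choice(np.arange(1_000, 10_000_000), size=n, replace=False)
    for i in range(n):
        chrom = str(int(rng.integers(1, 23)))
        ref, alt = rng.choice(list("ACGT"), size=2, replace=False)
        calls = {}
        for sid in sample_ids:
            r = rng.random()
            if r < 0.1:
                alleles = None
            elif r < 0.35:
                alleles = (0, 0)
            elif r < 0.8:
                alleles = (0, 1)
            else:
                alleles = (1, 1)
            depth = None if rng.random() < 0.1 else int(rng.integers(0, 200))
            calls[sid] = ts.GenotypeCall(sid, alleles, depth)
        af = None if rng.random() < 0.2 else float(rng.random() ** 3)
        cls = None if rng.random() < 0.2 else CLASSES[int(rng.integers(len(CLASSES)))]
        cons = None if rng.random() < 0.1 else CONSEQUENCES[int(rng.integers(len(CONSEQUENCES)))]
        ann = ts.AnnotationBundle(
            gene_symbol=f"G{i}", pop_af=af, classification=cls, consequence=cons,
        )
        records.append(
            ts.VariantRecord(
                chrom=chrom, pos=int(positions[i]), ref=str(ref), alt=str(alt),
                calls=calls, annotation=ann,
            )
        )
    return ts.VariantSet.from_records(records, sample_ids)
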