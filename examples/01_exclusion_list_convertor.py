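"""Exclusion List Convertor workflow: raw export -> clustered, merged,
instrument-ready CSV.

A raw exclusion export lists every precursor sampled across scans, so the
same peptide appears as several near-duplicate rows. We parse the export,
cluster rows that agree within 10 ppm and overlap in retention time, merge
the result with the previous iteration's list, and write the
``Mass,Start (min),End (min)`` CSV an instrument method editor imports.
"""

import io

from pieacq import (
    ExclusionList,
    cap_list,
    cluster_merge,
    export_instrument_table,
    merge_lists,
    parse_exclusion_export,
)

RAW_EXPORT = """m/z\tRT [min]\tCharge\tIntensity
500.0000\t30.00\t2\t1.2e5
500.0030\t30.40\t2\t9.8e4
500.0045\t31.10\t2\t8.1e4
642.3312\t55.20\t3\t4.4e4
642.3390\t55.90\t3\t3.0e4
980.1200\t72.00\t2\t2.2e4
"""

entries = parse_exclusion_export(io.StringIO(RAW_EXPORT), rt_pad=2.0)
print(f"parsed {len(entries)} raw rows")

clustered = cluster_merge(entries, ppm_tolerance=10.0)
print(f"after 10 ppm / RT clustering: {len(clustered)} entries")
for e in clustered:
    print(f"  m/z {e.mz:.4f}  RT [{e.rt_start:.2f}, {e.rt_end:.2f}] min")

current = ExclusionList(clustered, ppm_tolerance=10.0, provenance=["run2"])
previous = ExclusionList(
    cluster_merge(
        parse_exclusion_export(
            io.StringIO("m/z\tRT [min]\n500.0010\t30.80\n777.7000\t40.00\n"), rt_pad=2.0
        ),
        10.0,
    ),
    ppm_tolerance=10.0,
    provenance=["run1"],
)
merged = cap_list(merge_lists(current, previous), max_entries=2000)
print(f"\nmerged with previous list: {len(merged)} entries, provenance {merged.provenance}")

buf = io.StringIO()
export_instrument_table(merged, buf)
print("\ninstrument import table:")
print(buf.getvalue())
# The 500-series rows collapse to one window: the instrument will skip that
# precursor over the whole merged RT range in the next iteration.
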