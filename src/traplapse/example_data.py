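"""Worked-example camera summary table from a published 10-camera seabird deployment.

The deployment monitored ground-nesting petrels with 10 time-lapse cameras
(hourly capture, infrared at night); 4483 images were annotated with the
classes Adult, Chick, and Egg.  The per-camera image counts, class counts,
and day/night class counts below are the printed summary statistics of that
deployment and serve as the package's worked-example input for the
partitioning bookkeeping: the raw imagery is not public, but the summary
table is all the partition objective needs (box-size categories excepted —
per-box areas were not printed, so the size term is zero on this input).
"""

from __future__ import annotations

import csv
import io

from traplapse.split import CameraStats

CLASSES = ("Adult", "Chick", "Egg")

#: camera, images, day images, night images, per-class totals, per-class day/night counts
CAMERA_TABLE_CSV = """\
camera_id,n_images,n_day_images,n_night_images,adult,chick,egg,adult_day,chick_day,egg_day,adult_night,chick_night,egg_night
ABC1,1072,708,364,1226,535,921,628,338,756,598,197,165
ABC2,224,126,98,350,33,34,198,11,47,152,22,9
ABC3,407,188,219,694,254,34,311,107,18,383,147,16
ABC4,365,302,63,661,64,475,461,31,463,200,33,12
ABC5,149,115,34,258,85,80,188,43,80,70,42,0
SWC1,308,305,3,129,0,403,127,0,401,2,0,2
SWC2,1330,1062,268,2795,570,1198,1807,288,1008,988,282,190
SWC3,506,372,134,1804,389,319,1079,221,279,725,168,40
SWC4,14,14,0,19,0,13,19,0,13,0,0,0
SWC5,108,59,49,162,103,0,57,56,0,105,47,0
"""

#: the deployment's published camera assignment (train/val/test)
REFERENCE_ASSIGNMENT = {
    "ABC1": "train", "ABC3": "train", "ABC5": "train",
    "SWC2": "train", "SWC4": "train", "SWC5": "train",
    "ABC2": "val", "ABC4": "val",
    "SWC1": "test", "SWC3": "test",
}

#: published subset image totals for the reference assignment
REFERENCE_SUBSET_IMAGES = {"train": 3080, "val": 589, "test": 814}

#: the camera forced into the training set (only 14 annotated images)
FORCED_TRAIN_CAMERA = "SWC4"


def example_camera_stats() -> list[CameraStats]:
    """Parse the printed summary table into :class:`CameraStats` objects."""
    stats = []
    for row in csv.DictReader(io.StringIO(CAMERA_TABLE_CSV)):
        stats.append(
            CameraStats(
                camera_id=row["camera_id"],
                n_images=int(row["n_images"]),
                class_counts={c: int(row[c.lower()]) for c in CLASSES},
                day_counts={c: int(row[f"{c.lower()}_day"]) for c in CLASSES},
                night_counts={c: int(row[f"{c.lower()}_night"]) for c in CLASSES},
            )
        )
    return stats
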