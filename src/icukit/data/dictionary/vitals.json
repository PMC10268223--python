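{
 "dbp": {
  "category": "Vitals",
  "class": "num_cncpt",
  "description": "diastolic blood pressure",
  "max": 200,
  "min": 0,
  "sources": {
   "aumc": [
    {
     "ids": [
      30002
     ],
     "sub_var": "itemid",
     "table": "numericitems"
    }
   ],
   "eav_absolute": [
    {
     "ids": [
      8368
     ],
     "sub_var": "itemid",
     "table": "chartevents"
    }
   ],
   "eav_relative": [
    {
     "ids": [
      202
     ],
     "sub_var": "itemid",
     "table": "observations"
    }
   ],
   "eicu": [
    {
     "ids": [
      20002
     ],
     "sub_var": "itemid",
     "table": "nursecharting"
    }
   ],
   "hirid": [
    {
     "ids": [
      40002
     ],
     "sub_var": "itemid",
     "table": "observations"
    }
   ],
   "miiv": [
    {
     "ids": [
      50002
     ],
     "sub_var": "itemid",
     "table": "chartevents"
    }
   ],
   "mimic": [
    {
     "ids": [
      10002
     ],
     "sub_var": "itemid",
     "table": "chartevents"
    }
   ],
   "wide_relative": [
    {
     "class": "col_itm",
     "table": "vitalperiodic",
     "val_var": "dbp"
    }
   ]
  },
  "target": "ts_tbl",
  "unit": [
   "mmHg"
  ]
 },
 "hr": {
  "category": "Vitals",
  "class": "num_cncpt",
  "description": "heart rate",
  "max": 300,
  "min": 0,
  "omopid": 4239408,
  "sources": {
   "aumc": [
    {
     "ids": [
      30000
     ],
     "sub_var": "itemid",
     "table": "numericitems"
    }
   ],
   "eav_absolute": [
    {
     "ids": [
      211,
      220045
     ],
     "sub_var": "itemid",
     "table": "chartevents"
    }
   ],
   "eav_relative": [
    {
     "ids": [
      200
     ],
     "sub_var": "itemid",
     "table": "observations"
    }
   ],
   "eicu": [
    {
     "ids": [
      20000
     ],
     "sub_var": "itemid",
     "table": "nursecharting"
    }
   ],
   "hirid": [
    {
     "ids": [
      40000
     ],
     "sub_var": "itemid",
     "table": "observations"
    }
   ],
   "miiv": [
    {
     "ids": [
      50000
     ],
     "sub_var": "itemid",
     "table": "chartevents"
    }
   ],
   "mimic": [
    {
     "ids": [
      10000
     ],
     "sub_var": "itemid",
     "table": "chartevents"
    }
   ],
   "wide_relative": [
    {
     "class": "col_itm",
     "table": "vitalperiodic",
     "val_var": "heartrate"
    }
   ]
  },
  "target": "ts_tbl",
  "unit": [
   "bpm",
   "/min"
  ]
 },
 "map": {
  "category": "Vitals",
  "class": "num_cncpt",
  "description": "mean arterial pressure",
  "max": 250,
  "min": 0,
  "sources": {
   "aumc": [
    {
     "ids": [
      30003
     ],
     "sub_var": "itemid",
     "table": "numericitems"
    }
   ],
   "eav_absolute": [
    {
     "ids": [
      52
     ],
     "sub_var": "itemid",
     "table": "chartevents"
    }
   ],
   "eav_relative": [
    {
     "ids": [
      203
     ],
     "sub_var": "itemid",
     "table": "observations"
    }
   ],
   "eicu": [
    {
     "ids": [
      20003
     ],
     "sub_var": "itemid",
     "table": "nursecharting"
    }
   ],
   "hirid": [
    {
     "ids": [
      40003
     ],
     "sub_var": "itemid",
     "table": "observations"
    }
   ],
   "miiv": [
    {
     "ids": [
      50003
     ],
     "sub_var": "itemid",
     "table": "chartevents"
    }
   ],
   "mimic": [
    {
     "ids": [
      10003
     ],
     "sub_var": "itemid",
     "table": "chartevents"
    }
   ],
   "wide_relative": [
    {
     "class": "col_itm",
     "table": "vitalperiodic",
     "val_var": "map"
    }
   ]
  },
  "target": "ts_tbl",
  "unit": [
   "mmHg"
  ]
 },
 "sbp": {
  "category": "Vitals",
  "class": "num_cncpt",
  "description": "systolic blood pressure",
  "max": 300,
  "min": 0,
  "sources": {
   "aumc": [
    {
     "ids": [
      30001
     ],
     "sub_var": "itemid",
     "table": "numericitems"
    }
   ],
   "eav_absolute": [
    {
     "ids": [
      51
     ],
     "sub_var": "itemid",
     "table": "chartevents"
    }
   ],
   "eav_relative": [
    {
     "ids": [
      201
     ],
     "sub_var": "itemid",
     "table": "observations"
    }
   ],
   "eicu": [
    {
     "ids": [
      20001
     ],
     "sub_var": "itemid",
     "table": "nursecharting"
    }
   ],
   "hirid": [
    {
     "ids": [
      40001
     ],
     "sub_var": "itemid",
     "table": "observations"
    }
   ],
   "miiv": [
    {
     "ids": [
      50001
     ],
     "sub_var": "itemid",
     "table": "chartevents"
    }
   ],
   "mimic": [
    {
     "ids": [
      10001
     ],
     "sub_var": "itemid",
     "table": "chartevents"
    }
   ],
   "wide_relative": [
    {
     "class": "col_itm",
     "table": "vitalperiodic",
     "val_var": "sbp"
    }
   ]
  },
  "target": "ts_tbl",
  "unit": [
   "mmHg"
  ]
 },
 "shock_idx": {
  "callback": "shock_idx_cb",
  "category": "Vitals",
  "class": "rec_cncpt",
  "concepts": [
   "hr",
   "sbp"
  ],
  "description": "shock index (HR/SBP)",
  "target": "ts_tbl"
 },
 "temp": {
  "category": "Vitals",
  "class": "num_cncpt",
  "description": "body temperature",
  "max": 45,
  "min": 25,
  "sources": {
   "aumc": [
    {
     "ids": [
      30004
     ],
     "sub_var": "itemid",
     "table": "numericitems"
    }
   ],
   "eav_absolute": [
    {
     "ids": [
      678
     ],
     "sub_var": "itemid",
     "table": "chartevents"
    }
   ],
   "eav_relative": [
    {
     "ids": [
      204
     ],
     "sub_var": "itemid",
     "table": "observations"
    }
   ],
   "eicu": [
    {
     "ids": [
      20004
     ],
     "sub_var": "itemid",
     "table": "nursecharting"
    }
   ],
   "hirid": [
    {
     "ids": [
      40004
     ],
     "sub_var": "itemid",
     "table": "observations"
    }
   ],
   "miiv": [
    {
     "ids": [
      50004
     ],
     "sub_var": "itemid",
     "table": "chartevents"
    }
   ],
   "mimic": [
    {
     "ids": [
      10004
     ],
     "sub_var": "itemid",
     "table": "chartevents"
    }
   ],
   "wide_relative": [
    {
     "class": "col_itm",
     "table": "vitalperiodic",
     "val_var": "temperature"
    }
   ]
  },
  "target": "ts_tbl",
  "unit": [
   "C"
  ]
 }
}
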