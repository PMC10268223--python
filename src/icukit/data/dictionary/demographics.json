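{
 "adm": {
  "category": "Demographics",
  "class": "fct_cncpt",
  "description": "admission type",
  "levels": [
   "med",
   "surg",
   "other"
  ],
  "sources": {
   "aumc": [
    {
     "ids": [
      30085
     ],
     "sub_var": "itemid",
     "table": "numericitems"
    }
   ],
   "eav_absolute": [
    {
     "class": "col_itm",
     "table": "admissions",
     "val_var": "admission_type"
    }
   ],
   "eav_relative": [
    {
     "class": "col_itm",
     "table": "general",
     "val_var": "admissiontype"
    }
   ],
   "eicu": [
    {
     "ids": [
      20085
     ],
     "sub_var": "itemid",
     "table": "nursecharting"
    }
   ],
   "miiv": [
    {
     "ids": [
      50085
     ],
     "sub_var": "itemid",
     "table": "chartevents"
    }
   ],
   "mimic": [
    {
     "ids": [
      10085
     ],
     "sub_var": "itemid",
     "table": "chartevents"
    }
   ],
   "wide_relative": [
    {
     "class": "col_itm",
     "table": "patient",
     "val_var": "admissiontype"
    }
   ]
  },
  "target": "id_tbl"
 },
 "age": {
  "category": "Demographics",
  "class": "num_cncpt",
  "description": "patient age",
  "max": 130,
  "min": 0,
  "sources": {
   "aumc": [
    {
     "ids": [
      30081
     ],
     "sub_var": "itemid",
     "table": "numericitems"
    }
   ],
   "eav_absolute": [
    {
     "class": "col_itm",
     "table": "patients",
     "val_var": "age"
    }
   ],
   "eav_relative": [
    {
     "class": "col_itm",
     "table": "general",
     "val_var": "age"
    }
   ],
   "eicu": [
    {
     "ids": [
      20081
     ],
     "sub_var": "itemid",
     "table": "nursecharting"
    }
   ],
   "hirid": [
    {
     "ids": [
      40081
     ],
     "sub_var": "itemid",
     "table": "observations"
    }
   ],
   "miiv": [
    {
     "ids": [
      50081
     ],
     "sub_var": "itemid",
     "table": "chartevents"
    }
   ],
   "mimic": [
    {
     "ids": [
      10081
     ],
     "sub_var": "itemid",
     "table": "chartevents"
    }
   ],
   "wide_relative": [
    {
     "class": "col_itm",
     "table": "patient",
     "val_var": "age"
    }
   ]
  },
  "target": "id_tbl",
  "unit": [
   "years"
  ]
 },
 "bmi": {
  "callback": "bmi_cb",
  "category": "Demographics",
  "class": "rec_cncpt",
  "concepts": [
   "height",
   "weight"
  ],
  "description": "body mass index",
  "target": "id_tbl"
 },
 "height": {
  "category": "Demographics",
  "class": "num_cncpt",
  "description": "patient height",
  "max": 250,
  "min": 50,
  "sources": {
   "aumc": [
    {
     "ids": [
      30083
     ],
     "sub_var": "itemid",
     "table": "numericitems"
    }
   ],
   "eav_absolute": [
    {
     "class": "col_itm",
     "table": "patients",
     "val_var": "height"
    }
   ],
   "eav_relative": [
    {
     "class": "col_itm",
     "table": "general",
     "val_var": "height"
    }
   ],
   "eicu": [
    {
     "ids": [
      20083
     ],
     "sub_var": "itemid",
     "table": "nursecharting"
    }
   ],
   "hirid": [
    {
     "ids": [
      40083
     ],
     "sub_var": "itemid",
     "table": "observations"
    }
   ],
   "miiv": [
    {
     "ids": [
      50083
     ],
     "sub_var": "itemid",
     "table": "chartevents"
    }
   ],
   "mimic": [
    {
     "ids": [
      10083
     ],
     "sub_var": "itemid",
     "table": "chartevents"
    }
   ],
   "wide_relative": [
    {
     "class": "col_itm",
     "table": "patient",
     "val_var": "admissionheight"
    }
   ]
  },
  "target": "id_tbl",
  "unit": [
   "cm"
  ]
 },
 "sex": {
  "category": "Demographics",
  "class": "fct_cncpt",
  "description": "patient sex",
  "levels": [
   "Male",
   "Female"
  ],
  "omopid": 37116947,
  "sources": {
   "aumc": [
    {
     "ids": [
      30082
     ],
     "sub_var": "itemid",
     "table": "numericitems"
    }
   ],
   "eav_absolute": [
    {
     "class": "col_itm",
     "table": "patients",
     "val_var": "sex"
    }
   ],
   "eav_relative": [
    {
     "class": "col_itm",
     "table": "general",
     "val_var": "sex"
    }
   ],
   "eicu": [
    {
     "ids": [
      20082
     ],
     "sub_var": "itemid",
     "table": "nursecharting"
    }
   ],
   "hirid": [
    {
     "ids": [
      40082
     ],
     "sub_var": "itemid",
     "table": "observations"
    }
   ],
   "miiv": [
    {
     "ids": [
      50082
     ],
     "sub_var": "itemid",
     "table": "chartevents"
    }
   ],
   "mimic": [
    {
     "ids": [
      10082
     ],
     "sub_var": "itemid",
     "table": "chartevents"
    }
   ],
   "wide_relative": [
    {
     "class": "col_itm",
     "table": "patient",
     "val_var": "gender"
    }
   ]
  },
  "target": "id_tbl"
 },
 "weight": {
  "category": "Demographics",
  "class": "num_cncpt",
  "description": "patient weight",
  "max": 500,
  "min": 1,
  "sources": {
   "aumc": [
    {
     "ids": [
      30084
     ],
     "sub_var": "itemid",
     "table": "numericitems"
    }
   ],
   "eav_absolute": [
    {
     "class": "col_itm",
     "table": "patients",
     "val_var": "weight"
    }
   ],
   "eav_relative": [
    {
     "class": "col_itm",
     "table": "general",
     "val_var": "weight"
    }
   ],
   "eicu": [
    {
     "ids": [
      20084
     ],
     "sub_var": "itemid",
     "table": "nursecharting"
    }
   ],
   "hirid": [
    {
     "ids": [
      40084
     ],
     "sub_var": "itemid",
     "table": "observations"
    }
   ],
   "miiv": [
    {
     "ids": [
      50084
     ],
     "sub_var": "itemid",
     "table": "chartevents"
    }
   ],
   "mimic": [
    {
     "ids": [
      10084
     ],
     "sub_var": "itemid",
     "table": "chartevents"
    }
   ],
   "wide_relative": [
    {
     "class": "col_itm",
     "table": "patient",
     "val_var": "admissionweight"
    }
   ]
  },
  "target": "id_tbl",
  "unit": [
   "kg"
  ]
 }
}
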