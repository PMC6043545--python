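org,gear,gear_subtype,source_unit,parameter,value,reference
WCPFC,purseseine,,days,,,duration reported directly as days
WCPFC,longline,,hooks,hooks_per_set,2750,standard longline set size
WCPFC,longline,,hooks,soak_hours,24,one set per day assumed
WCPFC,baitboat,,days,,,duration reported directly as days
IOTC,longline,ELL,hooks,hooks_per_set,1600,swordfish-target longline
IOTC,longline,ELL,hooks,soak_hours,24,one set per day assumed
IOTC,longline,FLL,hooks,hooks_per_set,1200,fresh longline
IOTC,longline,FLL,hooks,soak_hours,24,one set per day assumed
IOTC,longline,LL,hooks,hooks_per_set,2750,standard longline set size
IOTC,longline,LL,hooks,soak_hours,24,one set per day assumed
IOTC,longline,LLEX,hooks,hooks_per_set,2750,exploratory longline
IOTC,longline,LLEX,hooks,soak_hours,24,one set per day assumed
IOTC,longline,SLL,hooks,hooks_per_set,1600,shark-target longline
IOTC,longline,SLL,hooks,soak_hours,24,one set per day assumed
IOTC,purseseine,PS,hours,hours_per_day,24,fishing and search hours
IOTC,purseseine,PS,sets,sets_per_day,0.8,average incl. FAD sets
IOTC,purseseine,PSS,trips,days_per_trip,11,small purse seine 7-15 day trips
IOTC,baitboat,,trips,days_per_trip,16,pole-and-line trip duration
IOTC,gillnet,,trips,days_per_trip,30,gillnet 30-45 day trips
ICCAT,longline,,hooks,hooks_per_set,2750,comparable-gear set size
ICCAT,longline,,hooks,soak_hours,24,one set per day assumed
ICCAT,purseseine,,hours,hours_per_day,24,hours converted to days
ICCAT,baitboat,,days,,,duration reported directly as days
ICCAT,trap,,days,,,trap day equals day fished
ICCAT,troll,,days,,,duration reported directly as days
IATTC,longline,,hooks,hooks_per_set,1865,eastern Pacific longline set size
IATTC,longline,,hooks,soak_hours,19,observed soak time
IATTC,purseseine,,sets,sets_per_day,0.8,average incl. FAD sets
IATTC,baitboat,,sets,sets_per_day,5,approx. five school sets per day
CCSBT,longline,,hooks,hooks_per_set,2750,comparable-gear set size
CCSBT,longline,,hooks,soak_hours,22,observed soak time
CCSBT,purseseine,,hours,hours_per_day,24,hours converted to days
CCSBT,baitboat,,hours,hours_per_day,24,hours converted to days
ISC,longline,,hooks,hooks_per_set,2750,standard longline set size
ISC,longline,,hooks,soak_hours,24,one set per day assumed
ISC,purseseine,,days,,,duration reported directly as days
ISC,baitboat,,days,,,duration reported directly as days
ISC,troll,,days,,,duration reported directly as days
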